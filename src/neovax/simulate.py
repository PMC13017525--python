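"""Seeded synthetic-data generators with ground-truth labels.

Each generator emulates the statistical structure one pipeline stage
consumes — not biological realism:

* ``generate_cohort``       — coding transcripts with log-normal expression,
  somatic variants realizing requested consequence counts exactly, in-phase
  germline calls, an HLA typing, and optional planted strong binders for the
  mock predictor.
* ``simulate_elispot``      — negative-binomial well counts with a
  multiplicative post-vaccination effect for responder antigens.
* ``simulate_repertoires``  — power-law clone-size repertoires sampled
  multinomially pre/post vaccination with spiked expansions (de novo and
  pre-existing), paired-chain annotations and a reporter luminescence matrix
  consistent with the spiked truth.

All randomness flows from a single integer seed; regenerating with the same
spec and seed is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .antigen import (
    Consequence,
    GermlineVariantCall,
    SomaticVariant,
    TranscriptRecord,
    VariantKind,
    classify_variant,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]
_DEFAULT_HLA = [
    "A*01:01", "A*02:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02",
    "DRB1*04:01", "DRB1*07:01",
]


# ---------------------------------------------------------------------------
# Cohort (transcripts + variants + germline + HLA)
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    seed: int = 0
    patient_id: str = "P01"
    n_transcripts: int = 60
    cds_codons: tuple[int, int] = (120, 400)  # uniform range, excl. stop codon
    n_missense: int = 30
    n_frameshift: int = 4
    n_synonymous: int = 3
    n_nonsense: int = 2
    n_germline_in_phase: int = 2
    expression_log_mean: float = 2.0   # log-RPKM location
    expression_log_sigma: float = 1.5
    fraction_not_expressed: float = 0.1
    fraction_rna_vaf_zero: float = 0.1
    hla_alleles: tuple[str, ...] = tuple(_DEFAULT_HLA)
    planted_binders: tuple[tuple[str, str], ...] = ()


@dataclass
class Cohort:
    spec: CohortSpec
    transcripts: dict[str, TranscriptRecord]
    variants: list[SomaticVariant]
    germline_calls: list[GermlineVariantCall]
    hla_alleles: list[str]
    truth: pd.DataFrame  # variant_id, requested consequence


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons)
    return "ATG" + "".join(codons[1:]) + "TAA"


def _codon_substitutions(codon: str):
    """All (offset, alt_base, consequence) single-base edits of a codon."""
    ref_aa = str(Seq(codon).translate())
    for off in range(3):
        for base in "ACGT":
            if base == codon[off]:
                continue
            alt = codon[:off] + base + codon[off + 1 :]
            alt_aa = str(Seq(alt).translate())
            if alt_aa == ref_aa:
                kind = Consequence.SYNONYMOUS
            elif alt_aa == "*":
                kind = Consequence.NONSENSE
            else:
                kind = Consequence.MISSENSE
            yield off, base, kind


def _place_snv(
    rng: np.random.Generator,
    transcript: TranscriptRecord,
    want: Consequence,
    used_codons: set[tuple[str, int]],
) -> tuple[int, str, str] | None:
    """Find (cds_position, ref, alt) realizing ``want`` on the transcript."""
    n_codons = len(transcript.cds_sequence) // 3 - 1  # exclude stop codon
    order = rng.permutation(np.arange(1, n_codons))  # skip start codon
    for codon_idx in order:
        if (transcript.transcript_id, int(codon_idx)) in used_codons:
            continue
        codon = transcript.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
        options = [(o, b) for o, b, k in _codon_substitutions(codon) if k == want]
        if options:
            off, base = options[rng.integers(len(options))]
            used_codons.add((transcript.transcript_id, int(codon_idx)))
            pos = codon_idx * 3 + off + 1
            return int(pos), codon[off], base
    return None


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate one synthetic patient's design inputs (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    n_variants = spec.n_missense + spec.n_frameshift + spec.n_synonymous + spec.n_nonsense
    if n_variants > spec.n_transcripts * (spec.cds_codons[0] - 2):
        raise ValueError("more variants requested than available codons")

    transcripts: dict[str, TranscriptRecord] = {}
    for i in range(spec.n_transcripts):
        tid = f"TX{i:04d}"
        n_codons = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
        rpkm = float(np.exp(rng.normal(spec.expression_log_mean, spec.expression_log_sigma)))
        if rng.random() < spec.fraction_not_expressed:
            rpkm = 0.0
        transcripts[tid] = TranscriptRecord(
            transcript_id=tid,
            cds_sequence=_random_cds(rng, n_codons),
            expression_rpkm=rpkm,
            gene_symbol=f"GENE{i:04d}",
        )

    tids = list(transcripts)
    used_codons: set[tuple[str, int]] = set()
    variants: list[SomaticVariant] = []
    truth_rows = []

    def vafs():
        dna = float(rng.beta(2, 2) * 0.8 + 0.05)
        rna = 0.0 if rng.random() < spec.fraction_rna_vaf_zero else float(
            rng.beta(2, 2) * 0.8 + 0.05
        )
        return dna, rna

    requests = (
        [(Consequence.MISSENSE, spec.n_missense)]
        + [(Consequence.SYNONYMOUS, spec.n_synonymous)]
        + [(Consequence.NONSENSE, spec.n_nonsense)]
    )
    vid = 0
    for want, n in requests:
        placed = 0
        while placed < n:
            t = transcripts[tids[int(rng.integers(len(tids)))]]
            hit = _place_snv(rng, t, want, used_codons)
            if hit is None:
                continue
            pos, ref, alt = hit
            dna, rna = vafs()
            vid += 1
            variants.append(
                SomaticVariant(
                    variant_id=f"VAR{vid:04d}",
                    transcript_id=t.transcript_id,
                    kind=VariantKind.SNV,
                    cds_position=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    dna_vaf=dna,
                    rna_vaf=rna,
                    gene_symbol=t.gene_symbol,
                )
            )
            truth_rows.append((f"VAR{vid:04d}", want.value))
            placed += 1

    placed = 0
    while placed < spec.n_frameshift:
        t = transcripts[tids[int(rng.integers(len(tids)))]]
        # anchor well inside the CDS so the shifted frame has room for a tail
        max_anchor = len(t.cds_sequence) - 60
        pos = int(rng.integers(4, max_anchor))
        anchor = t.cds_sequence[pos - 1]
        if rng.random() < 0.5:
            ref, alt, kind = anchor, anchor + anchor, VariantKind.INSERTION
        else:
            ref, alt, kind = anchor + t.cds_sequence[pos], anchor, VariantKind.DELETION
        dna, rna = vafs()
        vid += 1
        variants.append(
            SomaticVariant(
                variant_id=f"VAR{vid:04d}",
                transcript_id=t.transcript_id,
                kind=kind,
                cds_position=pos,
                ref_allele=ref,
                alt_allele=alt,
                dna_vaf=dna,
                rna_vaf=rna,
                gene_symbol=t.gene_symbol,
            )
        )
        truth_rows.append((f"VAR{vid:04d}", Consequence.FRAMESHIFT.value))
        placed += 1

    # closed loop: requested consequences must be realized exactly
    for v, (_, want) in zip(variants, truth_rows):
        got = classify_variant(v, transcripts[v.transcript_id])
        if got.value != want:
            raise AssertionError(f"{v.variant_id}: requested {want}, realized {got.value}")

    germline_calls: list[GermlineVariantCall] = []
    missense = [v for v, (_, cons) in zip(variants, truth_rows) if cons == "missense"]
    for i, v in enumerate(missense[: spec.n_germline_in_phase]):
        t = transcripts[v.transcript_id]
        hit = _place_snv(rng, t, Consequence.MISSENSE, used_codons)
        if hit is None:
            continue
        pos, ref, alt = hit
        germline_calls.append(
            GermlineVariantCall(
                germline_id=f"GL{i + 1:03d}",
                transcript_id=t.transcript_id,
                cds_position=pos,
                ref_allele=ref,
                alt_allele=alt,
                in_phase_with=frozenset({v.variant_id}),
            )
        )

    return Cohort(
        spec=spec,
        transcripts=transcripts,
        variants=variants,
        germline_calls=germline_calls,
        hla_alleles=list(spec.hla_alleles),
        truth=pd.DataFrame(truth_rows, columns=["variant_id", "consequence"]),
    )


# ---------------------------------------------------------------------------
# ELISpot
# ---------------------------------------------------------------------------

@dataclass
class ElispotSimSpec:
    patient_id: str = "P01"
    n_antigens: int = 20
    n_responders: int = 6
    n_pre_existing: int = 1
    baseline_mean: float = 2.0
    dispersion: float = 5.0          # negative-binomial size parameter
    effect: float = 20.0             # post-vaccination multiplicative effect
    pre_existing_effect: float = 8.0  # baseline-positive antigens, pre-vaccination
    replicates: int = 3
    cells_per_well: float = 2e5
    timepoints: tuple[tuple[str, int], ...] = (("pre", 0), ("post", 85))

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.replicates not in (2, 3):
            raise ValueError("replicates must be 2 or 3")


def _nb(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_elispot(spec: ElispotSimSpec, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate-level ELISpot counts plus a truth table.

    Responder antigens gain a multiplicative ``effect`` post vaccination;
    pre-existing antigens are elevated at both timepoints (and further at
    post); non-responders share the medium-only control distribution.
    Returns (well-level frame, truth frame).
    """
    rng = np.random.default_rng(seed)
    antigens = [f"AG{i:03d}" for i in range(spec.n_antigens)]
    labels = (
        ["responder"] * spec.n_responders
        + ["pre_existing"] * spec.n_pre_existing
        + ["non_responder"] * (spec.n_antigens - spec.n_responders - spec.n_pre_existing)
    )
    rows = []
    for tp, day in spec.timepoints:
        for antigen, label in [("medium", "control")] + list(zip(antigens, labels)):
            mean = spec.baseline_mean
            if label == "responder" and tp != "pre":
                mean *= spec.effect
            elif label == "pre_existing":
                mean *= spec.pre_existing_effect if tp == "pre" else spec.pre_existing_effect * spec.effect
            counts = _nb(rng, mean, spec.dispersion, spec.replicates)
            for w, count in enumerate(counts):
                rows.append(
                    {
                        "patient_id": spec.patient_id,
                        "timepoint": tp,
                        "day": day,
                        "assay_arm": "ex_vivo",
                        "antigen_id": antigen,
                        "well_index": w + 1,
                        "count": int(count),
                        "tntc": False,
                        "cells_per_well": spec.cells_per_well,
                    }
                )
    truth = pd.DataFrame({"antigen_id": antigens, "truth": labels})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# TCR repertoires
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimSpec:
    patient_id: str = "P01"
    n_clones: int = 2000
    power_law_exponent: float = 1.5
    depth_pre: int = 30_000
    depth_post: int = 30_000
    depth_tumour: int = 5_000
    n_spiked_de_novo: int = 10
    n_spiked_pre_existing: int = 10
    expansion_fold: float = 100.0
    paired_probability: float = 0.8
    with_tumour: bool = True
    specific_fold_range: tuple[float, float] = (3.0, 20.0)
    nonspecific_fold_range: tuple[float, float] = (0.5, 1.5)
    control_rlu: float = 1000.0


@dataclass
class RepertoireSim:
    spec: RepertoireSimSpec
    pre: pd.DataFrame           # AIRR-style rearrangement rows
    post: pd.DataFrame
    tumour: pd.DataFrame | None
    single_cell: pd.DataFrame
    luminescence: pd.DataFrame
    truth: pd.DataFrame         # cdr3, spiked class, paired flag


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        core = "".join(rng.choice(list(_AA), size=int(rng.integers(7, 13))))
        cdr3 = f"CASS{core}F"
        if cdr3 not in existing:
            existing.add(cdr3)
            return cdr3


def _airr_frame(cdr3s: list[str], counts: np.ndarray, vj: dict[str, tuple[str, str]]) -> pd.DataFrame:
    keep = counts > 0
    return pd.DataFrame(
        {
            "junction_aa": np.asarray(cdr3s)[keep],
            "duplicate_count": counts[keep].astype(int),
            "v_call": [vj[c][0] for c in np.asarray(cdr3s)[keep]],
            "j_call": [vj[c][1] for c in np.asarray(cdr3s)[keep]],
            "locus": "TRB",
        }
    )


def simulate_repertoires(spec: RepertoireSimSpec, seed: int = 0) -> RepertoireSim:
    """Simulate pre/post (and tumour) bulk repertoires, single-cell pairing
    and a reporter matrix, with spiked expansions as ground truth."""
    n_spiked = spec.n_spiked_de_novo + spec.n_spiked_pre_existing
    if min(spec.depth_pre, spec.depth_post) < n_spiked:
        raise ValueError("sampling depth smaller than the number of spiked clones")
    rng = np.random.default_rng(seed)

    existing: set[str] = set()
    cdr3s = [_random_cdr3(rng, existing) for _ in range(spec.n_clones)]
    vj = {
        c: (f"TRBV{int(rng.integers(1, 31))}", f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}")
        for c in cdr3s
    }

    ranks = np.arange(1, spec.n_clones + 1, dtype=float)
    base_w = ranks ** -spec.power_law_exponent
    base_w /= base_w.sum()
    order = rng.permutation(spec.n_clones)  # decouple rank from clone identity
    base_w = base_w[order]

    # spiked pre-existing clones come from the better-sampled half so they are
    # reliably observed pre-treatment; de novo spikes are absent pre by design
    sorted_idx = np.argsort(base_w)[::-1]
    pre_existing_idx = rng.choice(
        sorted_idx[: spec.n_clones // 10], size=spec.n_spiked_pre_existing, replace=False
    )
    remaining = np.setdiff1d(sorted_idx, pre_existing_idx)
    de_novo_idx = rng.choice(remaining, size=spec.n_spiked_de_novo, replace=False)

    pre_w = base_w.copy()
    pre_w[de_novo_idx] = 0.0
    pre_w /= pre_w.sum()

    post_w = base_w.copy()
    post_w[pre_existing_idx] *= spec.expansion_fold
    post_w[de_novo_idx] = spec.expansion_fold * np.median(base_w)
    post_w /= post_w.sum()

    pre_counts = rng.multinomial(spec.depth_pre, pre_w)
    post_counts = rng.multinomial(spec.depth_post, post_w)
    # spiked clones are the ground truth; guarantee they are observed where
    # their construction says they must be
    pre_counts[pre_existing_idx] = np.maximum(pre_counts[pre_existing_idx], 1)
    spiked = np.concatenate([de_novo_idx, pre_existing_idx])
    post_counts[spiked] = np.maximum(post_counts[spiked], 1)

    tumour = None
    if spec.with_tumour:
        tumour_counts = rng.multinomial(spec.depth_tumour, post_w)
        tumour = _airr_frame(cdr3s, tumour_counts, vj)

    paired_flags = rng.random(spec.n_clones) < spec.paired_probability
    sc_rows = []
    clonotype_n = 0
    post_observed = np.flatnonzero(post_counts)
    for idx in post_observed:
        if not paired_flags[idx]:
            continue
        clonotype_n += 1
        cid = f"clonotype{clonotype_n}"
        cells = int(max(1, post_counts[idx] // 10))
        tra = f"CAV{''.join(rng.choice(list(_AA), size=8))}F"
        sc_rows.append((cid, "TRB", cdr3s[idx], vj[cdr3s[idx]][0], vj[cdr3s[idx]][1], cells))
        sc_rows.append((cid, "TRA", tra, f"TRAV{int(rng.integers(1, 41))}", f"TRAJ{int(rng.integers(1, 61))}", cells))
    # a few double-TRB artifacts that the paired-chain gate must discard
    for k in range(3):
        clonotype_n += 1
        cid = f"clonotype{clonotype_n}"
        for _ in range(2):
            sc_rows.append((cid, "TRB", _random_cdr3(rng, existing), "TRBV1", "TRBJ1-1", 1))
    single_cell = pd.DataFrame(
        sc_rows, columns=["clonotype_id", "chain", "cdr3_aa", "v_call", "j_call", "cell_count"]
    )

    truth = pd.DataFrame(
        {
            "trb_cdr3_aa": [cdr3s[i] for i in spiked],
            "spiked_class": ["de_novo"] * spec.n_spiked_de_novo
            + ["pre_existing"] * spec.n_spiked_pre_existing,
            "paired": [bool(paired_flags[i]) for i in spiked],
        }
    )

    # reporter matrix: one TCR per spiked paired clone (specific for its
    # antigen) plus matched non-specific TCR controls
    lum_rows = []
    antigens = [f"AG{i:03d}" for i in range(n_spiked)]
    for k, (idx, antigen) in enumerate(zip(spiked, antigens)):
        tcr = f"TCR_{cdr3s[idx]}"
        lum_rows.append((tcr, "none", "none", spec.control_rlu, True, cdr3s[idx]))
        specific = bool(paired_flags[idx])
        lo, hi = (
            spec.specific_fold_range if specific else spec.nonspecific_fold_range
        )
        fold = float(rng.uniform(lo, hi))
        lum_rows.append((tcr, antigen, "A*02:01", spec.control_rlu * fold, False, cdr3s[idx]))
    luminescence = pd.DataFrame(
        lum_rows, columns=["tcr_id", "antigen_id", "hla_allele", "rlu", "is_control", "trb_cdr3_aa"]
    )

    return RepertoireSim(
        spec=spec,
        pre=_airr_frame(cdr3s, pre_counts, vj),
        post=_airr_frame(cdr3s, post_counts, vj),
        tumour=tumour,
        single_cell=single_cell,
        luminescence=luminescence,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = cohort.spec.patient_id
    fasta = out / f"{pid}_transcripts.fasta"
    with open(fasta, "w") as fh:
        for t in cohort.transcripts.values():
            fh.write(f">{t.transcript_id}\n{t.cds_sequence}\n")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in cohort.transcripts.values()],
            "gene_symbol": [t.gene_symbol for t in cohort.transcripts.values()],
            "expression_rpkm": [t.expression_rpkm for t in cohort.transcripts.values()],
        }
    ).to_csv(out / f"{pid}_transcripts.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in cohort.variants],
            "transcript_id": [v.transcript_id for v in cohort.variants],
            "kind": [v.kind.value for v in cohort.variants],
            "cds_position": [v.cds_position for v in cohort.variants],
            "ref": [v.ref_allele for v in cohort.variants],
            "alt": [v.alt_allele for v in cohort.variants],
            "dna_vaf": [v.dna_vaf for v in cohort.variants],
            "rna_vaf": [v.rna_vaf for v in cohort.variants],
            "gene_symbol": [v.gene_symbol for v in cohort.variants],
        }
    ).to_csv(out / f"{pid}_variants.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "germline_id": [g.germline_id for g in cohort.germline_calls],
            "transcript_id": [g.transcript_id for g in cohort.germline_calls],
            "cds_position": [g.cds_position for g in cohort.germline_calls],
            "ref": [g.ref_allele for g in cohort.germline_calls],
            "alt": [g.alt_allele for g in cohort.germline_calls],
            "in_phase_with": [",".join(sorted(g.in_phase_with)) for g in cohort.germline_calls],
        }
    ).to_csv(out / f"{pid}_germline.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "patient_id": pid,
            "locus": [a.split("*")[0] for a in cohort.hla_alleles],
            "allele": cohort.hla_alleles,
        }
    ).to_csv(out / f"{pid}_hla.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / f"{pid}_variant_truth.tsv", sep="\t", index=False)
    return {
        "transcripts_fasta": str(fasta),
        "transcripts_tsv": str(out / f"{pid}_transcripts.tsv"),
        "variants_tsv": str(out / f"{pid}_variants.tsv"),
        "germline_tsv": str(out / f"{pid}_germline.tsv"),
        "hla_tsv": str(out / f"{pid}_hla.tsv"),
        "truth_tsv": str(out / f"{pid}_variant_truth.tsv"),
    }
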