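"""Vaccine target prioritization, selection and mRNA construct assembly.

Prioritization applies a staged filter to the candidate MPS pool. Only
mutations expressed in tumour RNA (RNA VAF > 0) enter the main stages:

1. up to 5 indel MPS, ranked by best HLA class I percentile score;
2. up to 20 SNV MPS with transcript expression >= 10 RPKM, ranked by best
   HLA class II score;
3. up to 20 SNV MPS with expression >= 1 RPKM, ranked by best class I score;
4. further SNV MPS by expression (descending) to reach 46 in total;

and, only if fewer than 46 were reached, mutations with RNA VAF = 0 are
appended — first by class I score where one exists (stage 5), then by
expression (stage 6). Each stage draws from candidates not selected by an
earlier stage; ties break by (score ascending, RPKM descending, variant id).

Up to 20 targets are then selected (by default the head of the prioritized
list), dealt alternately onto two mRNA strings of at most 10 targets, and
each string assembled into an open reading frame: secretion signal (SEC) ++
targets joined by 10-residue glycine/serine linkers (30 nt) ++ MHC class I
trafficking domain (MITD). Nucleotide sequences come from a fixed
most-frequent-human-codon table, so assembly is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .antigen import MutatedPeptideSequence, SomaticVariant, TranscriptRecord, translate_cds
from .epitopes import SENTINEL_SCORE, MpsScores

# Flanking domains fused to the neoantigen concatemer (amino-acid literals).
SEC = "MRVMAPRTLILLLSGALALTETWAGS"
MITD = "IVGIVAGLAVLAVVVIGAVVATVMCRRKSSGGKGGSYSQAASSDSAQGSDVSLTA"
#: RNA-stability element carried by the backbone; metadata, not part of the ORF.
FI_ELEMENT = "LVLHARNASCPFPVLGTPSLPRPRVPGMLPPPPAPLTTSASSRHL"

DEFAULT_LINKER = "GGSGGGGSGG"  # 10 aa glycine/serine linker -> 30 nt

PRIORITIZED_CAP = 46
SELECTION_CAP = 20
PER_STRING_CAP = 10
STEP1_INDEL_CAP = 5
STEP2_SNV_CAP = 20
STEP3_SNV_CAP = 20
STEP2_RPKM_MIN = 10.0
STEP3_RPKM_MIN = 1.0

#: Most-frequent human codon per amino acid; deterministic reverse translation.
CODON_TABLE: dict[str, str] = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}


def reverse_translate(protein: str, codon_table: dict[str, str] | None = None) -> str:
    table = codon_table or CODON_TABLE
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"no codon for residue {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class PrioritizedMps:
    mps: MutatedPeptideSequence
    selection_step: str  # s1_indel_hla1 .. s6_fallback_expression
    rank_within_step: int


@dataclass
class Construct:
    string_index: int
    target_ids: list[str]
    orf_aa: str
    orf_nt: str
    annotations: list[dict]  # 1-based inclusive aa/nt spans tiling the ORF


@dataclass
class VaccineDesign:
    patient_id: str
    prioritized: list[PrioritizedMps]
    selected: list[MutatedPeptideSequence]
    string_assignment: dict[str, int]  # mps_id -> 1 or 2
    constructs: list[Construct]
    fi_element: str = FI_ELEMENT
    config: dict = field(default_factory=dict)


class _Candidate:
    __slots__ = ("mps", "variant", "rpkm", "best1", "best2")

    def __init__(self, mps, variant, rpkm, scores: MpsScores):
        self.mps = mps
        self.variant = variant
        self.rpkm = rpkm
        self.best1 = scores.best_class1
        self.best2 = scores.best_class2


def _tiebreak(score):
    """Stable composite key: score asc, RPKM desc, variant id lexicographic."""
    return lambda c: (score(c), -c.rpkm, c.variant.variant_id)


def prioritize_mps(
    mps_list: list[MutatedPeptideSequence],
    scores: dict[str, MpsScores],
    transcripts: dict[str, TranscriptRecord],
    variants: list[SomaticVariant],
    cap: int = PRIORITIZED_CAP,
) -> list[PrioritizedMps]:
    """Staged prioritization of candidate MPS (see module docstring)."""
    variant_by_id = {v.variant_id: v for v in variants}
    cands: list[_Candidate] = []
    for mps in mps_list:
        if mps.mps_id not in scores:
            raise KeyError(f"MPS {mps.mps_id} has no binding scores")
        v = variant_by_id[mps.variant_id]
        rpkm = transcripts[v.transcript_id].expression_rpkm
        cands.append(_Candidate(mps, v, rpkm, scores[mps.mps_id]))

    expressed = [c for c in cands if c.variant.rna_vaf > 0]
    fallback = [c for c in cands if c.variant.rna_vaf == 0]

    picked: list[PrioritizedMps] = []
    picked_ids: set[str] = set()

    def take(pool, key, step, limit):
        n = 0
        for c in sorted(pool, key=key):
            if len(picked) >= cap or n >= limit:
                break
            if c.variant.variant_id in picked_ids:
                continue
            n += 1
            picked.append(PrioritizedMps(c.mps, step, n))
            picked_ids.add(c.variant.variant_id)

    indels = [c for c in expressed if c.variant.is_indel]
    snvs = [c for c in expressed if not c.variant.is_indel]

    take(indels, _tiebreak(lambda c: c.best1), "s1_indel_hla1", STEP1_INDEL_CAP)
    take(
        [c for c in snvs if c.rpkm >= STEP2_RPKM_MIN],
        _tiebreak(lambda c: c.best2),
        "s2_snv_hla2",
        STEP2_SNV_CAP,
    )
    take(
        [c for c in snvs if c.rpkm >= STEP3_RPKM_MIN],
        _tiebreak(lambda c: c.best1),
        "s3_snv_hla1",
        STEP3_SNV_CAP,
    )
    take(snvs, _tiebreak(lambda c: -c.rpkm), "s4_snv_expression", cap)

    if len(picked) < cap:
        with_score = [c for c in fallback if c.best1 < SENTINEL_SCORE]
        without = [c for c in fallback if c.best1 >= SENTINEL_SCORE]
        take(with_score, _tiebreak(lambda c: c.best1), "s5_fallback_hla1", cap)
        take(without, _tiebreak(lambda c: -c.rpkm), "s6_fallback_expression", cap)
    return picked


def select_targets(
    prioritized: list[PrioritizedMps],
    cap: int = SELECTION_CAP,
    weights: dict[str, float] | None = None,
    features: dict[str, dict[str, float]] | None = None,
) -> list[MutatedPeptideSequence]:
    """Select up to ``cap`` vaccine targets from the prioritized list.

    Default policy keeps the prioritized order. An optional composite
    re-ranking sorts (stably) by a weighted score over per-MPS features
    ``best_class1``/``best_class2`` (lower better) and ``rpkm``/``dna_vaf``
    (higher better); all-zero weights reduce to the default order.
    """
    if not prioritized:
        raise ValueError("cannot select targets from an empty prioritized list")
    order = list(prioritized)
    if weights and any(w != 0 for w in weights.values()) and features:
        def composite(p: PrioritizedMps) -> float:
            f = features[p.mps.mps_id]
            return (
                weights.get("best_class1", 0.0) * f.get("best_class1", 0.0)
                + weights.get("best_class2", 0.0) * f.get("best_class2", 0.0)
                - weights.get("rpkm", 0.0) * f.get("rpkm", 0.0)
                - weights.get("dna_vaf", 0.0) * f.get("dna_vaf", 0.0)
            )
        order = sorted(order, key=composite)
    return [p.mps for p in order[:cap]]


def partition_targets(selected: list[MutatedPeptideSequence]) -> dict[str, int]:
    """Deal targets alternately by selection rank onto two strings (<= 10 each)."""
    if not 1 <= len(selected) <= 2 * PER_STRING_CAP:
        raise ValueError(f"need 1..{2 * PER_STRING_CAP} targets, got {len(selected)}")
    return {mps.mps_id: 1 + i % 2 for i, mps in enumerate(selected)}


def assemble_construct(
    string_targets: list[MutatedPeptideSequence],
    linker_aa: str = DEFAULT_LINKER,
    codon_table: dict[str, str] | None = None,
    string_index: int = 1,
) -> Construct:
    """SEC ++ target concatemer with G/S linkers ++ MITD, with tiled spans."""
    if not string_targets:
        raise ValueError("cannot assemble a construct with no targets")
    if set(linker_aa) - set("GS") or len(linker_aa) != 10:
        raise ValueError("linker must be 10 residues of G/S only")

    parts: list[tuple[str, str, str]] = [("SEC", "SEC", SEC)]
    for i, mps in enumerate(string_targets):
        if i > 0:
            parts.append(("linker", f"linker_{i}", linker_aa))
        parts.append(("target", mps.mps_id, mps.sequence))
    parts.append(("MITD", "MITD", MITD))

    annotations, aa_pos = [], 1
    for kind, name, seq in parts:
        annotations.append(
            {
                "kind": kind,
                "name": name,
                "aa_start": aa_pos,
                "aa_end": aa_pos + len(seq) - 1,
                "nt_start": 3 * (aa_pos - 1) + 1,
                "nt_end": 3 * (aa_pos + len(seq) - 1),
            }
        )
        aa_pos += len(seq)
    orf_aa = "".join(seq for _, _, seq in parts)
    return Construct(
        string_index=string_index,
        target_ids=[m.mps_id for m in string_targets],
        orf_aa=orf_aa,
        orf_nt=reverse_translate(orf_aa, codon_table),
        annotations=annotations,
    )


def build_design(
    patient_id: str,
    mps_list: list[MutatedPeptideSequence],
    scores: dict[str, MpsScores],
    transcripts: dict[str, TranscriptRecord],
    variants: list[SomaticVariant],
    linker_aa: str = DEFAULT_LINKER,
    selection_cap: int = SELECTION_CAP,
) -> VaccineDesign:
    """Full chain: prioritize -> select -> partition -> assemble."""
    prioritized = prioritize_mps(mps_list, scores, transcripts, variants)
    selected = select_targets(prioritized, cap=selection_cap)
    assignment = partition_targets(selected)
    constructs = []
    for idx in (1, 2):
        targets = [m for m in selected if assignment[m.mps_id] == idx]
        if targets:
            constructs.append(assemble_construct(targets, linker_aa, string_index=idx))
    return VaccineDesign(
        patient_id=patient_id,
        prioritized=prioritized,
        selected=selected,
        string_assignment=assignment,
        constructs=constructs,
        config={"linker_aa": linker_aa, "selection_cap": selection_cap},
    )


def emit_design_report(
    design: VaccineDesign,
    out_dir: str | Path,
    scores: dict[str, MpsScores] | None = None,
    transcripts: dict[str, TranscriptRecord] | None = None,
    variants: list[SomaticVariant] | None = None,
) -> dict[str, Path]:
    """Write FASTA constructs, a target TSV with provenance and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = design.patient_id
    paths: dict[str, Path] = {}

    fasta = out_dir / f"{pid}_constructs.fasta"
    with open(fasta, "w") as fh:
        for c in design.constructs:
            fh.write(f">{pid}|string{c.string_index}|aa\n{c.orf_aa}\n")
            fh.write(f">{pid}|string{c.string_index}|nt\n{c.orf_nt}\n")
    paths["constructs_fasta"] = fasta

    variant_by_id = {v.variant_id: v for v in variants} if variants else {}
    step_by_id = {p.mps.mps_id: p.selection_step for p in design.prioritized}
    rows = []
    for rank, mps in enumerate(design.selected, start=1):
        v = variant_by_id.get(mps.variant_id)
        sc = scores.get(mps.mps_id) if scores else None
        rows.append(
            {
                "rank": rank,
                "mps_id": mps.mps_id,
                "variant_id": mps.variant_id,
                "string": design.string_assignment[mps.mps_id],
                "sequence": mps.sequence,
                "kind": mps.kind.value,
                "selection_step": step_by_id.get(mps.mps_id, ""),
                "best_class1": sc.best_class1 if sc else "",
                "best_class2": sc.best_class2 if sc else "",
                "rpkm": (
                    transcripts[v.transcript_id].expression_rpkm
                    if v and transcripts
                    else ""
                ),
                "dna_vaf": v.dna_vaf if v else "",
                "rna_vaf": v.rna_vaf if v else "",
            }
        )
    targets_tsv = out_dir / f"{pid}_targets.tsv"
    pd.DataFrame(rows).to_csv(targets_tsv, sep="\t", index=False)
    paths["targets_tsv"] = targets_tsv

    manifest = {
        "patient_id": pid,
        "config": design.config,
        "config_hash": hashlib.sha256(
            json.dumps(design.config, sort_keys=True).encode()
        ).hexdigest(),
        "n_prioritized": len(design.prioritized),
        "n_selected": len(design.selected),
        "strings": {
            str(c.string_index): {"n_targets": len(c.target_ids), "orf_nt_len": len(c.orf_nt)}
            for c in design.constructs
        },
        "fi_element": design.fi_element,
    }
    manifest_json = out_dir / f"{pid}_manifest.json"
    manifest_json.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest_json"] = manifest_json
    return paths


def validate_design(design: VaccineDesign) -> None:
    """Structural invariants; raises AssertionError on violation."""
    assert len(design.prioritized) <= PRIORITIZED_CAP
    assert len(design.selected) <= SELECTION_CAP
    vids = [m.variant_id for m in design.selected]
    assert len(vids) == len(set(vids)), "duplicate variant selected"
    for idx in (1, 2):
        n = sum(1 for s in design.string_assignment.values() if s == idx)
        assert n <= PER_STRING_CAP
    for c in design.constructs:
        expected = len(SEC) + len(MITD) + sum(
            len(m.sequence) for m in design.selected if m.mps_id in c.target_ids
        ) + 10 * (len(c.target_ids) - 1)
        assert len(c.orf_aa) == expected
        assert translate_cds(c.orf_nt + "TAA") == c.orf_aa
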