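"""Mutated peptide sequence (MPS) construction from somatic variants.

A vaccine candidate peptide is derived from each protein-changing somatic
variant on its designated canonical transcript:

* SNVs (and in-frame indels): the window of up to 13 residues on each side
  of the changed amino acid — a 27mer when the mutation is interior, shorter
  at protein termini where only the available flank is kept.
* Frameshift indels: the novel sequence from the first changed amino acid to
  the next stop codon, hard-capped at 50 residues.

Protein-changing germline variants that are in phase with the somatic
mutation (phasing supplied as input flags) are applied inside the window so
the vaccine encodes the peptide actually present in the tumour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

SNV_FLANK = 13  # residues kept on each side of a substituted amino acid
FRAMESHIFT_CAP = 50  # maximum length of a frameshift neo-ORF peptide

_VALID_NT = frozenset("ACGT")


class VariantKind(str, Enum):
    SNV = "snv"
    INSERTION = "insertion"
    DELETION = "deletion"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"


class MpsKind(str, Enum):
    SNV = "snv"
    FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class TranscriptRecord:
    """A coding transcript: CDS (including terminal stop codon) plus expression."""

    transcript_id: str
    cds_sequence: str
    expression_rpkm: float
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        cds = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", cds)
        if len(cds) < 6 or len(cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length must be >= 6 and divisible by 3, "
                f"got {len(cds)}"
            )
        bad = set(cds) - _VALID_NT
        if bad:
            raise ValueError(f"{self.transcript_id}: non-ACGT symbols {sorted(bad)}")
        if self.expression_rpkm < 0:
            raise ValueError(f"{self.transcript_id}: negative RPKM")
        aa = str(Seq(cds).translate())
        if "*" in aa[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon in CDS")

    @property
    def protein(self) -> str:
        """Translation of the CDS with the terminal stop dropped."""
        return translate_cds(self.cds_sequence)


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic variant in CDS coordinates (1-based, VCF-style anchoring).

    For insertions and deletions ``ref`` and ``alt`` both include the anchor
    base at ``cds_position`` (e.g. deletion of T after pos 10: ref="CT",
    alt="C" at position 10).
    """

    variant_id: str
    transcript_id: str
    kind: VariantKind
    cds_position: int
    ref_allele: str
    alt_allele: str
    dna_vaf: float
    rna_vaf: float
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.kind == VariantKind.SNV and not (
            len(self.ref_allele) == len(self.alt_allele) == 1
        ):
            raise ValueError(f"{self.variant_id}: SNV requires single-base ref/alt")
        if self.cds_position < 1:
            raise ValueError(f"{self.variant_id}: cds_position must be 1-based")
        for name, v in (("dna_vaf", self.dna_vaf), ("rna_vaf", self.rna_vaf)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.variant_id}: {name}={v} outside [0, 1]")

    @property
    def is_indel(self) -> bool:
        return self.kind in (VariantKind.INSERTION, VariantKind.DELETION)


@dataclass(frozen=True)
class GermlineVariantCall:
    """A protein-changing germline SNV with phasing flags supplied as input."""

    germline_id: str
    transcript_id: str
    cds_position: int
    ref_allele: str
    alt_allele: str
    in_phase_with: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class MutatedPeptideSequence:
    mps_id: str
    variant_id: str
    sequence: str
    mutation_positions: frozenset[int]  # 1-based indices into `sequence`
    kind: MpsKind
    incorporated_germline: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.mutation_positions:
            raise ValueError(f"{self.mps_id}: MPS must contain >= 1 mutated position")
        if "*" in self.sequence:
            raise ValueError(f"{self.mps_id}: MPS contains a stop symbol")
        if any(p < 1 or p > len(self.sequence) for p in self.mutation_positions):
            raise ValueError(f"{self.mps_id}: mutation position outside sequence")


def translate_cds(cds: str, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the standard genetic code; terminal stop dropped.

    With ``allow_internal_stop`` (frameshift re-translation path) translation
    stops at the first stop codon instead of raising. A trailing partial
    codon (possible after a frameshift) is ignored.
    """
    cds = cds.upper()
    bad = set(cds) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGT symbol(s) in CDS: {sorted(bad)}")
    trimmed = cds[: len(cds) - len(cds) % 3]
    if allow_internal_stop:
        return str(Seq(trimmed).translate(to_stop=True))
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in CDS")
    return aa


def apply_variant_to_cds(cds: str, variant: SomaticVariant) -> str:
    """Return the mutated CDS. Ref alleles are checked against the transcript."""
    p = variant.cds_position
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if p + len(ref) - 1 > len(cds):
        raise ValueError(f"{variant.variant_id}: variant extends past CDS end")
    observed = cds[p - 1 : p - 1 + len(ref)]
    if observed != ref:
        raise ValueError(
            f"{variant.variant_id}: ref allele {ref!r} does not match CDS "
            f"({observed!r} at position {p})"
        )
    return cds[: p - 1] + alt + cds[p - 1 + len(ref) :]


def classify_variant(variant: SomaticVariant, transcript: TranscriptRecord) -> Consequence:
    """Consequence of a somatic variant on its transcript's protein."""
    if variant.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"{variant.variant_id}: transcript mismatch "
            f"({variant.transcript_id} vs {transcript.transcript_id})"
        )
    if variant.cds_position > len(transcript.cds_sequence):
        raise ValueError(f"{variant.variant_id}: position outside CDS")
    indel_len = len(variant.alt_allele) - len(variant.ref_allele)
    if indel_len != 0:
        return Consequence.FRAMESHIFT if indel_len % 3 else Consequence.INFRAME_INDEL
    codon_idx = (variant.cds_position - 1) // 3
    cds = transcript.cds_sequence
    mutated = apply_variant_to_cds(cds, variant)
    ref_aa = str(Seq(cds[codon_idx * 3 : codon_idx * 3 + 3]).translate())
    alt_aa = str(Seq(mutated[codon_idx * 3 : codon_idx * 3 + 3]).translate())
    if alt_aa == ref_aa:
        return Consequence.SYNONYMOUS
    if alt_aa == "*":
        return Consequence.NONSENSE
    return Consequence.MISSENSE


def build_mps_snv(
    protein: str,
    mutated_index: int,
    germline_substitutions: dict[int, str] | None = None,
    *,
    mps_id: str = "mps",
    variant_id: str = "variant",
    germline_ids: tuple[str, ...] = (),
    flags: tuple[str, ...] = (),
) -> MutatedPeptideSequence:
    """27mer window around a substituted residue of the mutated protein.

    ``protein`` is the somatically mutated protein; ``mutated_index`` is the
    1-based position of the changed residue. At the termini the window is
    truncated to the available flank (no padding). In-phase germline
    substitutions (protein position -> residue) falling inside the window are
    applied to the emitted sequence and recorded as additional mutated
    positions.
    """
    if not 1 <= mutated_index <= len(protein):
        raise ValueError(f"mutated_index {mutated_index} outside protein [1, {len(protein)}]")
    start = max(1, mutated_index - SNV_FLANK)  # 1-based inclusive
    end = min(len(protein), mutated_index + SNV_FLANK)
    window = list(protein[start - 1 : end])
    positions = {mutated_index - start + 1}
    applied: list[str] = []
    for prot_pos, residue in sorted((germline_substitutions or {}).items()):
        if start <= prot_pos <= end and prot_pos != mutated_index:
            window[prot_pos - start] = residue
            positions.add(prot_pos - start + 1)
            applied.append(str(prot_pos))
    return MutatedPeptideSequence(
        mps_id=mps_id,
        variant_id=variant_id,
        sequence="".join(window),
        mutation_positions=frozenset(positions),
        kind=MpsKind.SNV,
        incorporated_germline=germline_ids,
        flags=flags,
    )


def build_mps_frameshift(
    mutated_tail: str,
    *,
    mps_id: str = "mps",
    variant_id: str = "variant",
    flags: tuple[str, ...] = (),
) -> MutatedPeptideSequence:
    """Frameshift MPS: novel tail up to the next stop, capped at 50 residues.

    ``mutated_tail`` is the re-translated shifted frame from the first changed
    residue to (not including) the stop codon. Every emitted position is
    mutated. An empty tail (immediate stop) raises; the caller discards the
    variant with a logged reason.
    """
    if not mutated_tail:
        raise ValueError("frameshift produced an empty tail (immediate stop)")
    seq = mutated_tail[:FRAMESHIFT_CAP]
    return MutatedPeptideSequence(
        mps_id=mps_id,
        variant_id=variant_id,
        sequence=seq,
        mutation_positions=frozenset(range(1, len(seq) + 1)),
        kind=MpsKind.FRAMESHIFT,
        flags=flags,
    )


def _germline_substitutions(
    transcript: TranscriptRecord,
    somatic_id: str,
    germline_calls: list[GermlineVariantCall],
) -> tuple[dict[int, str], tuple[str, ...]]:
    """Protein substitutions from germline SNVs in phase with ``somatic_id``."""
    subs: dict[int, str] = {}
    ids: list[str] = []
    for g in germline_calls:
        if g.transcript_id != transcript.transcript_id or somatic_id not in g.in_phase_with:
            continue
        if len(g.ref_allele) != 1 or len(g.alt_allele) != 1:
            log.warning("germline %s: only SNV germline calls are applied; skipped", g.germline_id)
            continue
        codon_idx = (g.cds_position - 1) // 3
        codon = list(transcript.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3])
        codon[(g.cds_position - 1) % 3] = g.alt_allele.upper()
        new_aa = str(Seq("".join(codon)).translate())
        if new_aa == "*":
            log.warning("germline %s introduces a stop; skipped", g.germline_id)
            continue
        if new_aa != transcript.protein[codon_idx]:
            subs[codon_idx + 1] = new_aa
            ids.append(g.germline_id)
    return subs, tuple(ids)


def build_patient_mps(
    transcripts: dict[str, TranscriptRecord] | list[TranscriptRecord],
    variants: list[SomaticVariant],
    germline_calls: list[GermlineVariantCall] | None = None,
) -> list[MutatedPeptideSequence]:
    """One MPS per protein-changing somatic variant on its canonical transcript.

    Synonymous and nonsense variants are removed. Variants on non-expressed
    transcripts (RPKM == 0) are retained but flagged ``not_expressed`` —
    expression gating belongs to prioritization, not construction.
    """
    if not isinstance(transcripts, dict):
        transcripts = {t.transcript_id: t for t in transcripts}
    germline_calls = germline_calls or []
    missing = sorted({v.transcript_id for v in variants} - set(transcripts))
    if missing:
        raise KeyError(f"variants reference missing transcripts: {missing}")

    out: list[MutatedPeptideSequence] = []
    for v in variants:
        t = transcripts[v.transcript_id]
        consequence = classify_variant(v, t)
        if consequence in (Consequence.SYNONYMOUS, Consequence.NONSENSE):
            log.info("variant %s filtered: %s", v.variant_id, consequence.value)
            continue
        flags = ("not_expressed",) if t.expression_rpkm == 0 else ()
        mps_id = f"MPS_{v.variant_id}"
        if consequence == Consequence.FRAMESHIFT:
            mutated = translate_cds(apply_variant_to_cds(t.cds_sequence, v), allow_internal_stop=True)
            wt = t.protein
            diff = _first_difference(wt, mutated)
            if diff is None:
                log.warning("variant %s discarded: frameshift yields no novel residue", v.variant_id)
                continue
            out.append(
                build_mps_frameshift(
                    mutated[diff:], mps_id=mps_id, variant_id=v.variant_id, flags=flags
                )
            )
        else:
            # missense SNV or in-frame indel: windowed like an SNV around the
            # first changed residue of the mutated protein
            mutated = translate_cds(apply_variant_to_cds(t.cds_sequence, v), allow_internal_stop=True)
            diff = _first_difference(t.protein, mutated)
            if diff is None:
                log.warning("variant %s discarded: no residue change", v.variant_id)
                continue
            subs, gids = _germline_substitutions(t, v.variant_id, germline_calls)
            out.append(
                build_mps_snv(
                    mutated,
                    diff + 1,
                    subs,
                    mps_id=mps_id,
                    variant_id=v.variant_id,
                    germline_ids=gids,
                    flags=flags,
                )
            )
    return out


def _first_difference(wt: str, mutated: str) -> int | None:
    """0-based index of the first differing residue, or None if mutated is a
    (possibly truncated) copy of wt."""
    for i, (a, b) in enumerate(zip(wt, mutated)):
        if a != b:
            return i
    if len(mutated) > len(wt):
        return len(wt)
    return None


# ---------------------------------------------------------------------------
# File interfaces: FASTA + TSV sidecar for transcripts, TSV for variants/MPS
# ---------------------------------------------------------------------------

def read_transcripts(fasta_path: str | Path, tsv_path: str | Path) -> dict[str, TranscriptRecord]:
    from Bio import SeqIO

    meta = pd.read_csv(tsv_path, sep="\t", dtype={"transcript_id": str}, float_precision="round_trip")
    meta = meta.set_index("transcript_id")
    out: dict[str, TranscriptRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        out[rec.id] = TranscriptRecord(
            transcript_id=rec.id,
            cds_sequence=str(rec.seq),
            expression_rpkm=float(row["expression_rpkm"]),
            gene_symbol=str(row.get("gene_symbol", "")),
        )
    return out


def read_variants(tsv_path: str | Path) -> list[SomaticVariant]:
    df = pd.read_csv(
        tsv_path, sep="\t", dtype={"variant_id": str, "transcript_id": str},
        float_precision="round_trip",
    )
    return [
        SomaticVariant(
            variant_id=r.variant_id,
            transcript_id=r.transcript_id,
            kind=VariantKind(r.kind),
            cds_position=int(r.cds_position),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            dna_vaf=float(r.dna_vaf),
            rna_vaf=float(r.rna_vaf),
            gene_symbol=str(getattr(r, "gene_symbol", "")),
        )
        for r in df.itertuples()
    ]


def read_germline_calls(tsv_path: str | Path) -> list[GermlineVariantCall]:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    return [
        GermlineVariantCall(
            germline_id=r.germline_id,
            transcript_id=r.transcript_id,
            cds_position=int(r.cds_position),
            ref_allele=r.ref,
            alt_allele=r.alt,
            in_phase_with=frozenset(str(r.in_phase_with).split(",")) if r.in_phase_with else frozenset(),
        )
        for r in df.itertuples()
    ]


def mps_table(mps_list: list[MutatedPeptideSequence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mps_id": [m.mps_id for m in mps_list],
            "variant_id": [m.variant_id for m in mps_list],
            "sequence": [m.sequence for m in mps_list],
            "mutation_positions": [
                ",".join(map(str, sorted(m.mutation_positions))) for m in mps_list
            ],
            "kind": [m.kind.value for m in mps_list],
            "incorporated_germline": [",".join(m.incorporated_germline) for m in mps_list],
            "flags": [",".join(m.flags) for m in mps_list],
        }
    )


def write_mps_table(mps_list: list[MutatedPeptideSequence], path: str | Path) -> None:
    mps_table(mps_list).to_csv(path, sep="\t", index=False)
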