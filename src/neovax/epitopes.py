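"""Variant-containing epitope enumeration and HLA-binding scoring.

For each mutated peptide sequence (MPS), every 8–11mer window overlapping at
least one mutated residue is scored against the patient's HLA-A/B/C alleles
(class I) and every 15mer window against the HLA-DRB alleles (class II).
Scores follow the percentile-rank convention of consensus MHC-binding
predictors: lower is stronger. The best (minimum) score per class is
associated with the MPS and drives prioritization.

Real binding predictors are external tools; the module defines a minimal
``BindingPredictor`` protocol and ships a deterministic mock whose scores are
a keyed hash of (peptide, allele, seed), with optional planted strong
binders for closed-loop tests.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Iterable, Protocol

import pandas as pd

from .antigen import MutatedPeptideSequence

CLASS1_LENGTHS = (8, 9, 10, 11)
CLASS2_LENGTH = 15
#: Score recorded when a class has no scoreable peptides (e.g. MPS < 15 aa
#: for class II); sorts after every genuine percentile score.
SENTINEL_SCORE = 999.0

_CLASS1_LOCI = ("A", "B", "C")
_CLASS2_PREFIX = "DRB"


def normalize_allele(allele: str) -> str:
    """Normalize common HLA allele spellings to e.g. ``A*02:01`` / ``DRB1*04:01``."""
    a = allele.strip().upper().replace("HLA-", "")
    if "*" not in a:
        m = re.match(r"^([A-Z]+[0-9]?)(\d{2}:\d{2,}[A-Z]?)$", a)
        if m:
            a = f"{m.group(1)}*{m.group(2)}"
    if not re.match(r"^[A-Z]+[0-9]?\*\d{2,}:\d{2,}[A-Z]?$", a):
        raise ValueError(f"unrecognized HLA allele: {allele!r}")
    return a


def allele_class(allele: str) -> str:
    """HLA class of a normalized allele: 'I' for A/B/C, 'II' for DRB."""
    locus = allele.split("*")[0]
    if locus in _CLASS1_LOCI:
        return "I"
    if locus.startswith(_CLASS2_PREFIX):
        return "II"
    raise ValueError(f"allele {allele} is neither HLA-A/B/C nor HLA-DRB")


@dataclass(frozen=True)
class EpitopeQuery:
    mps_id: str
    peptide: str
    start: int  # 1-based start within the MPS
    hla_allele: str
    hla_class: str  # "I" or "II"


class BindingPredictor(Protocol):
    """Deterministic (peptide, allele) -> percentile-like score, lower = stronger."""

    name: str

    def predict(self, peptide: str, allele: str) -> float: ...


class MockPredictor:
    """Keyed-hash stand-in for external MHC-binding prediction tools.

    The score for (peptide, allele) is ``sha256(f"{peptide}|{allele}|{seed}")``
    mapped uniformly onto [0, 100]. Pairs listed in ``planted_binders`` are
    forced to ``planted_score`` (default 0.1), so tests can construct MPS with
    a known best score.
    """

    def __init__(
        self,
        seed: int = 0,
        planted_binders: Iterable[tuple[str, str]] = (),
        planted_score: float = 0.1,
    ) -> None:
        self.name = f"mock(seed={seed})"
        self.seed = seed
        self.planted = {(p, normalize_allele(a)) for p, a in planted_binders}
        self.planted_score = planted_score

    def predict(self, peptide: str, allele: str) -> float:
        allele = normalize_allele(allele)
        if (peptide, allele) in self.planted:
            return self.planted_score
        digest = hashlib.sha256(f"{peptide}|{allele}|{self.seed}".encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64 * 100.0


def _windows(mps: MutatedPeptideSequence, length: int) -> list[tuple[int, str]]:
    """(1-based start, peptide) for every length-`length` window that overlaps
    at least one mutated position."""
    seq, muts = mps.sequence, mps.mutation_positions
    out = []
    for start in range(1, len(seq) - length + 2):
        if any(start <= m <= start + length - 1 for m in muts):
            out.append((start, seq[start - 1 : start + length - 1]))
    return out


def enumerate_class1(mps: MutatedPeptideSequence) -> list[tuple[int, str]]:
    """All variant-containing 8–11mers of the MPS, as (start, peptide)."""
    out: list[tuple[int, str]] = []
    for k in CLASS1_LENGTHS:
        if k <= len(mps.sequence):
            out.extend(_windows(mps, k))
    return out


def enumerate_class2(mps: MutatedPeptideSequence) -> list[tuple[int, str]]:
    """All variant-containing 15mers of the MPS (empty when the MPS is shorter)."""
    if len(mps.sequence) < CLASS2_LENGTH:
        return []
    return _windows(mps, CLASS2_LENGTH)


@dataclass
class MpsScores:
    mps_id: str
    best_class1: float
    best_class2: float


def score_mps(
    mps: MutatedPeptideSequence,
    patient_hla: Iterable[str],
    predictor: BindingPredictor,
) -> tuple[pd.DataFrame, MpsScores]:
    """Score every variant-containing peptide against the patient's alleles.

    Returns the full score table (one row per peptide x allele) and the
    per-MPS best scores: the minimum over class I rows and over class II
    rows; a class with no rows gets :data:`SENTINEL_SCORE`.
    """
    alleles = [normalize_allele(a) for a in patient_hla]
    class1 = [a for a in alleles if allele_class(a) == "I"]
    class2 = [a for a in alleles if allele_class(a) == "II"]
    rows = []
    for start, peptide in enumerate_class1(mps):
        for allele in class1:
            rows.append((mps.mps_id, peptide, start, allele, "I", predictor.predict(peptide, allele)))
    for start, peptide in enumerate_class2(mps):
        for allele in class2:
            rows.append((mps.mps_id, peptide, start, allele, "II", predictor.predict(peptide, allele)))
    table = pd.DataFrame(
        rows, columns=["mps_id", "peptide", "start", "allele", "hla_class", "score"]
    )
    best1 = float(table.loc[table.hla_class == "I", "score"].min()) if (table.hla_class == "I").any() else SENTINEL_SCORE
    best2 = float(table.loc[table.hla_class == "II", "score"].min()) if (table.hla_class == "II").any() else SENTINEL_SCORE
    return table, MpsScores(mps.mps_id, best1, best2)


def score_all(
    mps_list: list[MutatedPeptideSequence],
    patient_hla: Iterable[str],
    predictor: BindingPredictor,
) -> tuple[pd.DataFrame, dict[str, MpsScores]]:
    """Score a full MPS list; returns the concatenated table and per-MPS bests."""
    alleles = list(patient_hla)
    tables, bests = [], {}
    for mps in mps_list:
        table, best = score_mps(mps, alleles, predictor)
        if not table.empty:
            tables.append(table)
        bests[mps.mps_id] = best
    combined = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["mps_id", "peptide", "start", "allele", "hla_class", "score"])
    )
    return combined, bests


def read_hla_typing(tsv_path) -> dict[str, list[str]]:
    """Read a patient HLA typing TSV (patient_id, locus, allele) -> alleles per patient."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    return {
        pid: [normalize_allele(a) for a in grp["allele"]]
        for pid, grp in df.groupby("patient_id")
    }
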