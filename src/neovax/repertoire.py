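"""Reverse immunomonitoring over bulk and single-cell TCR repertoires.

The TRB CDR3 amino-acid sequence is the clonotype identifier throughout:
bulk rearrangements with identical CDR3 are merged (counts and frequencies
summed), post-vaccination enrichment is the ratio of post to pre clone
frequency, and clones absent pre-treatment ("de novo") are imputed at the
lowest frequency observed in the pre-treatment repertoire. Only clonotypes
with paired TRA/TRB information from single-cell VDJ data are eligible for
candidate selection; the 10–15 most enriched clones per class (de novo /
pre-existing), at most 30 in total, go forward to TCR cloning. Reporter
(Jurkat-NFAT luciferase) read-outs call a TCR specific at a twofold
luminescence increase over its effectors-only control, and specific clones
are tracked across timepoints and tissue compartments by TRB CDR3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

PER_CLASS_MIN = 10
PER_CLASS_MAX = 15
TOTAL_MAX = 30
REACTIVITY_FOLD_CUTOFF = 2.0


class CloneStatus(str, Enum):
    DE_NOVO = "de_novo"
    PRE_EXISTING = "pre_existing"


@dataclass
class ClonotypeRepertoire:
    """CDR3-keyed clone counts and frequencies for one sample."""

    sample_id: str
    counts: dict[str, int]
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"{self.sample_id}: empty repertoire")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: counts must be >= 1")
        total = sum(self.counts.values())
        self.frequencies = {k: c / total for k, c in self.counts.items()}

    @property
    def min_frequency(self) -> float:
        return min(self.frequencies.values())


@dataclass(frozen=True)
class PairedClonotype:
    trb_cdr3_aa: str
    tra_cdr3_aa: str
    trb_v: str = ""
    trb_j: str = ""
    tra_v: str = ""
    tra_j: str = ""
    cell_count: int = 1


@dataclass
class EnrichmentRecord:
    trb_cdr3_aa: str
    pre_frequency: float
    post_frequency: float
    fold_change: float
    status: CloneStatus
    imputed_baseline: bool
    paired: bool = False


@dataclass
class ReactivityCall:
    tcr_id: str
    antigen_id: str
    hla_allele: str
    luminescence: float
    fold_over_control: float
    specific: bool


def merge_clonotypes(entries: list[tuple[str, int]], sample_id: str = "sample") -> ClonotypeRepertoire:
    """Merge raw rearrangement rows sharing a CDR3 aa sequence; frequencies
    are recomputed from the merged counts."""
    if not entries:
        raise ValueError("no clonotype entries to merge")
    counts: dict[str, int] = {}
    for cdr3, count in entries:
        if count < 1:
            raise ValueError(f"clonotype {cdr3}: count must be >= 1")
        counts[cdr3] = counts.get(cdr3, 0) + int(count)
    return ClonotypeRepertoire(sample_id=sample_id, counts=counts)


def compute_enrichment(
    pre: ClonotypeRepertoire, post: ClonotypeRepertoire
) -> list[EnrichmentRecord]:
    """Post-anchored clonal enrichment for every clone observed post-treatment.

    Clones also present pre-treatment are "pre-existing" with fold =
    post_f / pre_f; clones absent pre-treatment are "de novo" with the
    baseline imputed at the minimum frequency observed in the pre-treatment
    repertoire. Records are sorted by fold change descending (ties: higher
    post frequency first, then CDR3 lexicographic).
    """
    floor = pre.min_frequency
    records = []
    for cdr3, post_f in post.frequencies.items():
        pre_f = pre.frequencies.get(cdr3)
        if pre_f is None:
            records.append(
                EnrichmentRecord(cdr3, floor, post_f, post_f / floor, CloneStatus.DE_NOVO, True)
            )
        else:
            records.append(
                EnrichmentRecord(cdr3, pre_f, post_f, post_f / pre_f, CloneStatus.PRE_EXISTING, False)
            )
    records.sort(key=lambda r: (-r.fold_change, -r.post_frequency, r.trb_cdr3_aa))
    return records


def gate_paired(raw: pd.DataFrame) -> list[PairedClonotype]:
    """Keep only single-cell clonotypes with both a TRA and a TRB chain;
    clonotypes with two TRB chains are discarded.

    ``raw`` has one row per chain: columns clonotype_id, chain (TRA/TRB),
    cdr3_aa, v_call, j_call, cell_count. Multi-TRA clonotypes are retained;
    the TRA with the highest cell support is designated primary.
    """
    out = []
    for _, grp in raw.groupby("clonotype_id", sort=False):
        trb = grp[grp["chain"] == "TRB"]
        tra = grp[grp["chain"] == "TRA"]
        if len(trb) != 1 or len(tra) < 1:
            continue
        tra = tra.sort_values("cell_count", ascending=False).iloc[0]
        trb = trb.iloc[0]
        out.append(
            PairedClonotype(
                trb_cdr3_aa=trb["cdr3_aa"],
                tra_cdr3_aa=tra["cdr3_aa"],
                trb_v=str(trb.get("v_call", "")),
                trb_j=str(trb.get("j_call", "")),
                tra_v=str(tra.get("v_call", "")),
                tra_j=str(tra.get("j_call", "")),
                cell_count=int(grp["cell_count"].max()),
            )
        )
    return out


def rank_and_select(
    enrichments: list[EnrichmentRecord],
    paired: list[PairedClonotype] | set[str],
    per_class_max: int = PER_CLASS_MAX,
    total_max: int = TOTAL_MAX,
) -> list[EnrichmentRecord]:
    """Select cloning candidates: the most enriched paired clones per class.

    Only clonotypes with paired-chain information are eligible. Up to
    ``per_class_max`` de novo and ``per_class_max`` pre-existing clones are
    taken by fold change descending; scarcity in one class is not
    compensated by the other; ``total_max`` is enforced after per-class
    truncation.
    """
    if total_max < per_class_max:
        raise ValueError("total_max must be >= per_class_max")
    paired_set = (
        {p.trb_cdr3_aa for p in paired}
        if paired and isinstance(next(iter(paired)), PairedClonotype)
        else set(paired)
    )
    selected: list[EnrichmentRecord] = []
    for status in (CloneStatus.DE_NOVO, CloneStatus.PRE_EXISTING):
        pool = [r for r in enrichments if r.status == status and r.trb_cdr3_aa in paired_set]
        pool.sort(key=lambda r: (-r.fold_change, -r.post_frequency, r.trb_cdr3_aa))
        for r in pool[:per_class_max]:
            r.paired = True
            selected.append(r)
    selected.sort(key=lambda r: (-r.fold_change, -r.post_frequency, r.trb_cdr3_aa))
    return selected[:total_max]


def call_reactivity(
    luminescence: pd.DataFrame,
    fold_cutoff: float = REACTIVITY_FOLD_CUTOFF,
) -> list[ReactivityCall]:
    """Specificity calls from a Jurkat-NFAT reporter luminescence table.

    ``luminescence`` columns: tcr_id, antigen_id, hla_allele, rlu, is_control
    (boolean; the TCR-transfected effectors-only control row). Fold change is
    rlu / control rlu per TCR; specific iff fold >= ``fold_cutoff``.
    """
    calls = []
    for tcr_id, grp in luminescence.groupby("tcr_id", sort=False):
        controls = grp[grp["is_control"].astype(bool)]
        if controls.empty:
            raise ValueError(f"TCR {tcr_id}: no effectors-only control row")
        control_rlu = float(controls["rlu"].iloc[0])
        if control_rlu <= 0:
            raise ValueError(f"TCR {tcr_id}: control luminescence must be > 0")
        for _, row in grp[~grp["is_control"].astype(bool)].iterrows():
            fold = float(row["rlu"]) / control_rlu
            calls.append(
                ReactivityCall(
                    tcr_id=str(tcr_id),
                    antigen_id=str(row["antigen_id"]),
                    hla_allele=str(row["hla_allele"]),
                    luminescence=float(row["rlu"]),
                    fold_over_control=fold,
                    specific=fold >= fold_cutoff,
                )
            )
    return calls


def specific_tcrs(calls: list[ReactivityCall]) -> set[str]:
    """TCRs specific for at least one (antigen, HLA) condition."""
    return {c.tcr_id for c in calls if c.specific}


def track_clones(
    clones: list[str],
    repertoires: dict[str, ClonotypeRepertoire],
) -> pd.DataFrame:
    """Frequency matrix (clone x sample) with 0 where a clone is absent,
    plus a ``cumulative`` row summing the tracked clones per sample."""
    samples = list(repertoires)
    data = {
        s: [repertoires[s].frequencies.get(c, 0.0) for c in clones] for s in samples
    }
    df = pd.DataFrame(data, index=clones)
    df.loc["cumulative"] = df.sum(axis=0)
    return df


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_bulk_repertoire(path, sample_id: str | None = None) -> ClonotypeRepertoire:
    """Read a bulk repertoire from an AIRR rearrangement TSV (junction_aa,
    duplicate_count) or a simplified TSV with columns cdr3_aa, count."""
    df = pd.read_csv(path, sep="\t")
    if "junction_aa" in df.columns:
        cdr3_col, count_col = "junction_aa", "duplicate_count"
    elif "cdr3_aa" in df.columns:
        cdr3_col, count_col = "cdr3_aa", "count"
    else:
        raise ValueError(f"{path}: expected 'junction_aa' (AIRR) or 'cdr3_aa' column")
    if "locus" in df.columns:
        df = df[df["locus"] == "TRB"]
    entries = [(str(r[cdr3_col]), int(r[count_col])) for _, r in df.iterrows()]
    return merge_clonotypes(entries, sample_id=sample_id or str(path))


def read_single_cell_clonotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"clonotype_id", "chain", "cdr3_aa", "cell_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trb_cdr3_aa": [r.trb_cdr3_aa for r in records],
            "pre_frequency": [r.pre_frequency for r in records],
            "post_frequency": [r.post_frequency for r in records],
            "fold_change": [r.fold_change for r in records],
            "status": [r.status.value for r in records],
            "imputed_baseline": [r.imputed_baseline for r in records],
            "paired": [r.paired for r in records],
        }
    )
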