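import numpy as np
import pandas as pd
import pytest

from neovax.repertoire import (
    CloneStatus,
    ClonotypeRepertoire,
    EnrichmentRecord,
    call_reactivity,
    compute_enrichment,
    gate_paired,
    merge_clonotypes,
    rank_and_select,
    specific_tcrs,
    track_clones,
)


class TestMerge:
    def test_identical_cdr3_summed(self):
        rep = merge_clonotypes([("CASSLGQYF", 3), ("CASSLGQYF", 7), ("CASSXF", 10)])
        assert rep.counts["CASSLGQYF"] == 10
        assert rep.frequencies["CASSLGQYF"] == pytest.approx(0.5)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        entries = [(f"CASS{i}F", int(rng.integers(1, 50))) for i in range(200)]
        rep = merge_clonotypes(entries)
        assert sum(rep.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rep = merge_clonotypes([("CASSAF", 3), ("CASSBF", 7), ("CASSAF", 2)])
        again = merge_clonotypes(list(rep.counts.items()))
        assert again.counts == rep.counts and again.frequencies == rep.frequencies

    def test_empty_or_invalid_rejected(self):
        with pytest.raises(ValueError):
            merge_clonotypes([])
        with pytest.raises(ValueError):
            merge_clonotypes([("CASSAF", 0)])


class TestEnrichment:
    def repertoires(self):
        pre = ClonotypeRepertoire("pre", {"A": 10, "B": 100, "C": 9889, "RARE": 1})
        post = ClonotypeRepertoire("post", {"A": 100, "B": 100, "NEW": 50, "C": 9750})
        return pre, post

    def test_pre_existing_fold(self):
        pre = ClonotypeRepertoire("pre", {"A": 1, "X": 999})
        post = ClonotypeRepertoire("post", {"A": 10, "X": 990})
        rec = {r.trb_cdr3_aa: r for r in compute_enrichment(pre, post)}["A"]
        assert rec.fold_change == pytest.approx(10.0)
        assert rec.status == CloneStatus.PRE_EXISTING and not rec.imputed_baseline

    def test_de_novo_imputed_at_pre_minimum(self):
        pre, post = self.repertoires()
        rec = {r.trb_cdr3_aa: r for r in compute_enrichment(pre, post)}["NEW"]
        assert rec.status == CloneStatus.DE_NOVO and rec.imputed_baseline
        assert rec.pre_frequency == pytest.approx(1 / 10000)
        assert rec.fold_change == pytest.approx((50 / 10000) / (1 / 10000))

    def test_post_anchored(self):
        pre, post = self.repertoires()
        assert "RARE" not in {r.trb_cdr3_aa for r in compute_enrichment(pre, post)}

    def test_empty_pre_rejected(self):
        with pytest.raises(ValueError):
            ClonotypeRepertoire("pre", {})

    def test_fold_invariant_to_depth_rescaling(self):
        pre = ClonotypeRepertoire("pre", {"A": 10, "B": 90})
        post = ClonotypeRepertoire("post", {"A": 40, "B": 60})
        pre10 = ClonotypeRepertoire("pre", {"A": 100, "B": 900})
        post10 = ClonotypeRepertoire("post", {"A": 400, "B": 600})
        f = {r.trb_cdr3_aa: r.fold_change for r in compute_enrichment(pre, post)}
        f10 = {r.trb_cdr3_aa: r.fold_change for r in compute_enrichment(pre10, post10)}
        assert f == pytest.approx(f10)

    def test_de_novo_fold_decreases_with_higher_floor(self):
        post = ClonotypeRepertoire("post", {"NEW": 5, "B": 95})
        shallow = ClonotypeRepertoire("pre", {"B": 99, "X": 1})      # floor 0.01
        deep = ClonotypeRepertoire("pre", {"B": 9999, "X": 1})       # floor 1e-4
        f_shallow = compute_enrichment(shallow, post)[0].fold_change
        f_deep = compute_enrichment(deep, post)[0].fold_change
        assert f_deep > f_shallow

    def test_sorted_by_fold_descending(self):
        pre, post = self.repertoires()
        folds = [r.fold_change for r in compute_enrichment(pre, post)]
        assert folds == sorted(folds, reverse=True)


def sc_frame(rows):
    return pd.DataFrame(rows, columns=["clonotype_id", "chain", "cdr3_aa", "v_call", "j_call", "cell_count"])


class TestPairedGate:
    def test_gating_rules(self):
        raw = sc_frame([
            ("c1", "TRA", "CAVF", "TRAV1", "TRAJ1", 5),
            ("c1", "TRB", "CASSAF", "TRBV1", "TRBJ1", 5),
            ("c2", "TRB", "CASSBF", "TRBV1", "TRBJ1", 3),      # TRB only
            ("c3", "TRA", "CAVXF", "TRAV1", "TRAJ1", 2),       # TRA only
            ("c4", "TRB", "CASSCF", "TRBV1", "TRBJ1", 2),      # two TRB
            ("c4", "TRB", "CASSDF", "TRBV2", "TRBJ1", 2),
            ("c4", "TRA", "CAVYF", "TRAV1", "TRAJ1", 2),
        ])
        kept = gate_paired(raw)
        assert [p.trb_cdr3_aa for p in kept] == ["CASSAF"]
        assert kept[0].tra_cdr3_aa == "CAVF"

    def test_multi_tra_keeps_best_supported(self):
        raw = sc_frame([
            ("c1", "TRB", "CASSAF", "TRBV1", "TRBJ1", 9),
            ("c1", "TRA", "CAVLOW", "TRAV1", "TRAJ1", 2),
            ("c1", "TRA", "CAVHIGH", "TRAV2", "TRAJ2", 7),
        ])
        (kept,) = gate_paired(raw)
        assert kept.tra_cdr3_aa == "CAVHIGH"


def enrichment(cdr3, fold, status):
    return EnrichmentRecord(
        trb_cdr3_aa=cdr3,
        pre_frequency=1e-5,
        post_frequency=fold * 1e-5,
        fold_change=fold,
        status=status,
        imputed_baseline=status == CloneStatus.DE_NOVO,
    )


class TestSelection:
    def test_full_pools_give_15_plus_15(self):
        recs = [enrichment(f"D{i}", 100 - i, CloneStatus.DE_NOVO) for i in range(50)]
        recs += [enrichment(f"P{i}", 100 - i, CloneStatus.PRE_EXISTING) for i in range(50)]
        paired = {r.trb_cdr3_aa for r in recs}
        out = rank_and_select(recs, paired)
        assert len(out) == 30
        by_class = {s: sum(1 for r in out if r.status == s) for s in CloneStatus}
        assert by_class[CloneStatus.DE_NOVO] == 15
        assert by_class[CloneStatus.PRE_EXISTING] == 15
        # the most enriched of each class are the ones selected
        assert {r.trb_cdr3_aa for r in out if r.status == CloneStatus.DE_NOVO} == {
            f"D{i}" for i in range(15)
        }

    def test_scarce_class_not_borrowed(self):
        recs = [enrichment(f"D{i}", 50 + i, CloneStatus.DE_NOVO) for i in range(4)]
        recs += [enrichment(f"P{i}", 100 - i, CloneStatus.PRE_EXISTING) for i in range(40)]
        out = rank_and_select(recs, {r.trb_cdr3_aa for r in recs})
        assert sum(1 for r in out if r.status == CloneStatus.DE_NOVO) == 4
        assert sum(1 for r in out if r.status == CloneStatus.PRE_EXISTING) == 15
        assert len(out) == 19

    def test_unpaired_never_selected(self):
        recs = [enrichment("UNPAIRED", 1e6, CloneStatus.DE_NOVO)]
        recs += [enrichment(f"P{i}", 10, CloneStatus.PRE_EXISTING) for i in range(3)]
        out = rank_and_select(recs, {f"P{i}" for i in range(3)})
        assert "UNPAIRED" not in {r.trb_cdr3_aa for r in out}
        assert all(r.paired for r in out)

    def test_inconsistent_caps_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select([], set(), per_class_max=15, total_max=10)


class TestReactivity:
    def lum(self, rows):
        return pd.DataFrame(
            rows, columns=["tcr_id", "antigen_id", "hla_allele", "rlu", "is_control"]
        )

    def test_twofold_boundary(self):
        calls = call_reactivity(self.lum([
            ("t1", "none", "none", 1000.0, True),
            ("t1", "AG1", "A*02:01", 2000.0, False),
            ("t1", "AG2", "A*02:01", 1990.0, False),
        ]))
        by_ag = {c.antigen_id: c for c in calls}
        assert by_ag["AG1"].specific and by_ag["AG1"].fold_over_control == pytest.approx(2.0)
        assert not by_ag["AG2"].specific
        assert specific_tcrs(calls) == {"t1"}

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            call_reactivity(self.lum([
                ("t1", "none", "none", 0.0, True),
                ("t1", "AG1", "A*02:01", 500.0, False),
            ]))

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            call_reactivity(self.lum([("t1", "AG1", "A*02:01", 500.0, False)]))


class TestTracking:
    def test_frequency_matrix(self):
        reps = {
            "pre": ClonotypeRepertoire("pre", {"A": 1, "B": 999}),
            "post": ClonotypeRepertoire("post", {"A": 20, "B": 980}),
            "tumour": ClonotypeRepertoire("tumour", {"B": 10}),
        }
        m = track_clones(["A", "B"], reps)
        assert m.loc["A", "pre"] == pytest.approx(0.001)
        assert m.loc["A", "post"] == pytest.approx(0.02)
        assert m.loc["A", "tumour"] == 0.0  # absent in tumour -> explicit zero
        assert (m.loc["cumulative"] <= 1.0 + 1e-9).all()

    def test_cumulative_row_is_sum(self):
        reps = {"s": ClonotypeRepertoire("s", {"A": 25, "B": 25, "C": 50})}
        m = track_clones(["A", "B"], reps)
        assert m.loc["cumulative", "s"] == pytest.approx(0.5)
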