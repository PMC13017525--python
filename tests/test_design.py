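import json

import numpy as np
import pytest

from neovax.antigen import (
    MpsKind,
    MutatedPeptideSequence,
    SomaticVariant,
    TranscriptRecord,
    VariantKind,
    translate_cds,
)
from neovax.design import (
    DEFAULT_LINKER,
    MITD,
    SEC,
    assemble_construct,
    build_design,
    emit_design_report,
    partition_targets,
    prioritize_mps,
    reverse_translate,
    select_targets,
    validate_design,
)
from neovax.epitopes import SENTINEL_SCORE, MpsScores

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_candidate(i, kind, rpkm, best1, best2, rna_vaf):
    """One MPS + its variant + transcript + scores, on its own transcript."""
    rng = np.random.default_rng(i)
    seq = "".join(rng.choice(list(AA), size=27))
    vid, tid, mid = f"v{i:03d}", f"t{i:03d}", f"m{i:03d}"
    mps = MutatedPeptideSequence(
        mid, vid, seq, frozenset({14}),
        MpsKind.FRAMESHIFT if kind != VariantKind.SNV else MpsKind.SNV,
    )
    variant = SomaticVariant(
        variant_id=vid, transcript_id=tid, kind=kind, cds_position=10,
        ref_allele="A" if kind == VariantKind.SNV else "AT",
        alt_allele="G" if kind == VariantKind.SNV else "A",
        dna_vaf=0.3, rna_vaf=rna_vaf,
    )
    codons = reverse_translate("M" + "".join(rng.choice(list(AA), size=40)))
    transcript = TranscriptRecord(tid, codons + "TAA", rpkm)
    return mps, variant, transcript, MpsScores(mid, best1, best2)


def build_instance(specs):
    """specs: list of (kind, rpkm, best1, best2, rna_vaf)."""
    mps_list, variants, transcripts, scores = [], [], {}, {}
    for i, (kind, rpkm, b1, b2, vaf) in enumerate(specs):
        m, v, t, s = make_candidate(i, kind, rpkm, b1, b2, vaf)
        mps_list.append(m)
        variants.append(v)
        transcripts[t.transcript_id] = t
        scores[m.mps_id] = s
    return mps_list, variants, transcripts, scores


def brute_force_prioritize(specs, cap=46):
    """Independent re-application of the staged rules on explicit tuples.

    Returns [(candidate index, step)] in selection order.
    """
    idx = list(range(len(specs)))
    expressed = [i for i in idx if specs[i][4] > 0]
    fallback = [i for i in idx if specs[i][4] == 0]
    picked, steps = [], []

    def key(i, score):
        return (score, -specs[i][1], f"v{i:03d}")

    def take(pool, score_of, step, limit):
        chosen = sorted(pool, key=lambda i: key(i, score_of(i)))
        n = 0
        for i in chosen:
            if len(picked) >= cap or n >= limit or i in picked:
                continue
            picked.append(i)
            steps.append(step)
            n += 1

    indels = [i for i in expressed if specs[i][0] != VariantKind.SNV]
    snvs = [i for i in expressed if specs[i][0] == VariantKind.SNV]
    take(indels, lambda i: specs[i][2], "s1_indel_hla1", 5)
    take([i for i in snvs if specs[i][1] >= 10], lambda i: specs[i][3], "s2_snv_hla2", 20)
    take([i for i in snvs if specs[i][1] >= 1], lambda i: specs[i][2], "s3_snv_hla1", 20)
    take(snvs, lambda i: -specs[i][1], "s4_snv_expression", cap)
    if len(picked) < cap:
        with_score = [i for i in fallback if specs[i][2] < SENTINEL_SCORE]
        without = [i for i in fallback if specs[i][2] >= SENTINEL_SCORE]
        take(with_score, lambda i: specs[i][2], "s5_fallback_hla1", cap)
        take(without, lambda i: -specs[i][1], "s6_fallback_expression", cap)
    return list(zip(picked, steps))


def random_specs(rng, n):
    specs = []
    for _ in range(n):
        kind = [VariantKind.SNV, VariantKind.INSERTION, VariantKind.DELETION][
            rng.choice(3, p=[0.7, 0.15, 0.15])
        ]
        rpkm = float(rng.choice([0.0, 0.5, 5.0, 15.0, 120.0]))
        b1 = float(rng.uniform(0.1, 60))
        b2 = float(rng.choice([rng.uniform(0.1, 60), SENTINEL_SCORE]))
        vaf = float(rng.choice([0.0, 0.4], p=[0.3, 0.7]))
        specs.append((kind, rpkm, b1, b2, vaf))
    return specs


class TestPrioritize:
    def test_indel_step_cap_of_5(self):
        specs = [(VariantKind.INSERTION, 20.0, float(i), 5.0, 0.5) for i in range(7)]
        m, v, t, s = build_instance(specs)
        out = prioritize_mps(m, s, t, v)
        s1 = [p for p in out if p.selection_step == "s1_indel_hla1"]
        assert len(s1) == 5
        # the five best (lowest) class I scores win
        assert [p.mps.mps_id for p in s1] == [f"m{i:03d}" for i in range(5)]

    def test_rpkm_gate_between_steps_2_and_3(self):
        # RPKM 9.9 is refused by the >=10 class II stage but admitted by the
        # >=1 class I stage
        specs = [(VariantKind.SNV, 9.9, 0.2, 0.2, 0.5)]
        m, v, t, s = build_instance(specs)
        out = prioritize_mps(m, s, t, v)
        assert out[0].selection_step == "s3_snv_hla1"

    def test_abundant_pool_yields_exactly_46(self):
        rng = np.random.default_rng(0)
        specs = [
            (VariantKind.SNV, float(rng.uniform(1, 100)), float(rng.uniform(0, 50)),
             float(rng.uniform(0, 50)), 0.5)
            for _ in range(200)
        ]
        m, v, t, s = build_instance(specs)
        assert len(prioritize_mps(m, s, t, v)) == 46

    def test_scarce_pool_smaller_than_cap(self):
        # with < 46 candidates the list ends smaller than the cap and never
        # duplicates a variant; expressed indels beyond the stage-1 cap of 5
        # are the only candidates the staged rules can leave behind
        rng = np.random.default_rng(1)
        specs = random_specs(rng, 40)
        m, v, t, s = build_instance(specs)
        out = prioritize_mps(m, s, t, v)
        got = [(int(p.mps.mps_id[1:]), p.selection_step) for p in out]
        assert got == brute_force_prioritize(specs)
        assert len(out) <= 46
        left_out = set(range(40)) - {i for i, _ in got}
        n_expressed_indels = sum(
            1 for k, _, _, _, vaf in specs if k != VariantKind.SNV and vaf > 0
        )
        assert all(specs[i][0] != VariantKind.SNV and specs[i][4] > 0 for i in left_out)
        assert len(left_out) == max(0, n_expressed_indels - 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_equivalence_with_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        specs = random_specs(rng, int(rng.integers(3, 16)))
        m, v, t, s = build_instance(specs)
        got = [(int(p.mps.mps_id[1:]), p.selection_step) for p in prioritize_mps(m, s, t, v)]
        assert got == brute_force_prioritize(specs)

    def test_missing_scores_raise(self):
        m, v, t, s = build_instance([(VariantKind.SNV, 5.0, 1.0, 1.0, 0.5)])
        with pytest.raises(KeyError, match="m000"):
            prioritize_mps(m, {}, t, v)

    def test_monotone_in_class1_score(self):
        # improving one candidate's class I score never evicts it from a
        # class-I-ranked stage it already won
        specs = [(VariantKind.INSERTION, 20.0, float(i + 1), 5.0, 0.5) for i in range(6)]
        m, v, t, s = build_instance(specs)
        winners = {
            p.mps.mps_id for p in prioritize_mps(m, s, t, v) if p.selection_step == "s1_indel_hla1"
        }
        assert "m002" in winners
        s["m002"] = MpsScores("m002", 0.01, 5.0)
        improved = {
            p.mps.mps_id for p in prioritize_mps(m, s, t, v) if p.selection_step == "s1_indel_hla1"
        }
        assert "m002" in improved


class TestSelectPartition:
    def test_selection_caps(self):
        rng = np.random.default_rng(2)
        specs = random_specs(rng, 100)
        m, v, t, s = build_instance(specs)
        out = prioritize_mps(m, s, t, v)
        selected = select_targets(out)
        assert len(selected) == 20
        assert selected == [p.mps for p in out[:20]]
        assert len(select_targets(out[:12])) == 12

    def test_empty_prioritized_raises(self):
        with pytest.raises(ValueError):
            select_targets([])

    def test_zero_weights_identical_to_default(self):
        rng = np.random.default_rng(3)
        specs = random_specs(rng, 30)
        m, v, t, s = build_instance(specs)
        out = prioritize_mps(m, s, t, v)
        feats = {p.mps.mps_id: {"best_class1": 1.0} for p in out}
        assert select_targets(out, weights={"best_class1": 0.0}, features=feats) == select_targets(out)

    def test_partition_balanced(self):
        def targets(n):
            return [
                MutatedPeptideSequence(f"m{i}", f"v{i}", "A" * 20 + "WYWYWYW", frozenset({1}), MpsKind.SNV)
                for i in range(n)
            ]

        a = partition_targets(targets(20))
        assert sum(1 for v in a.values() if v == 1) == 10
        b = partition_targets(targets(13))
        assert sorted((sum(1 for v in b.values() if v == k)) for k in (1, 2)) == [6, 7]
        c = partition_targets(targets(1))
        assert list(c.values()) == [1]
        with pytest.raises(ValueError):
            partition_targets(targets(21))


class TestAssembly:
    def mps(self, i, length=27):
        seq = "".join(AA[(i + j) % 20] for j in range(length))
        return MutatedPeptideSequence(f"m{i}", f"v{i}", seq, frozenset({1}), MpsKind.SNV)

    def test_two_target_lengths(self):
        c = assemble_construct([self.mps(0), self.mps(1)])
        assert len(c.orf_aa) == 26 + 27 + 10 + 27 + 55 == 145
        assert len(c.orf_nt) == 435
        assert c.orf_aa.startswith(SEC) and c.orf_aa.endswith(MITD)

    def test_single_target_no_linker(self):
        c = assemble_construct([self.mps(0)])
        assert not any(a["kind"] == "linker" for a in c.annotations)
        assert len(c.orf_aa) == 26 + 27 + 55

    def test_linker_spans_are_30_nt(self):
        c = assemble_construct([self.mps(i) for i in range(4)])
        linkers = [a for a in c.annotations if a["kind"] == "linker"]
        assert len(linkers) == 3
        for a in linkers:
            assert a["nt_end"] - a["nt_start"] + 1 == 30
            assert set(c.orf_aa[a["aa_start"] - 1 : a["aa_end"]]) <= set("GS")

    def test_annotations_tile_orf(self):
        c = assemble_construct([self.mps(i) for i in range(3)])
        pos = 1
        for a in c.annotations:
            assert a["aa_start"] == pos
            pos = a["aa_end"] + 1
        assert pos - 1 == len(c.orf_aa)

    def test_orf_translates_back(self):
        c = assemble_construct([self.mps(0), self.mps(1)])
        assert translate_cds(c.orf_nt + "TAA") == c.orf_aa

    def test_bad_linker_rejected(self):
        with pytest.raises(ValueError):
            assemble_construct([self.mps(0)], linker_aa="GGSGGGGSGA")
        with pytest.raises(ValueError):
            assemble_construct([self.mps(0)], linker_aa="GGS")

    def test_orf_length_identity(self):
        targets = [self.mps(i, length=14 + i) for i in range(5)]
        c = assemble_construct(targets)
        assert len(c.orf_aa) == 81 + sum(len(t.sequence) for t in targets) + 10 * 4


class TestReport:
    @pytest.fixture
    def design_and_inputs(self):
        rng = np.random.default_rng(4)
        specs = random_specs(rng, 60)
        m, v, t, s = build_instance(specs)
        d = build_design("P01", m, s, t, v)
        validate_design(d)
        return d, s, t, v

    def test_report_round_trip(self, design_and_inputs, tmp_path):
        from Bio import SeqIO
        import pandas as pd

        d, s, t, v = design_and_inputs
        paths = emit_design_report(d, tmp_path, s, t, v)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["constructs_fasta"]), "fasta")}
        for c in d.constructs:
            assert records[f"P01|string{c.string_index}|aa"] == c.orf_aa
            assert records[f"P01|string{c.string_index}|nt"] == c.orf_nt
        table = pd.read_csv(paths["targets_tsv"], sep="\t")
        assert list(table.mps_id) == [mps.mps_id for mps in d.selected]
        assert set(table.string) <= {1, 2}
        manifest = json.loads(paths["manifest_json"].read_text())
        assert manifest["n_selected"] == len(d.selected)

    def test_report_deterministic(self, design_and_inputs, tmp_path):
        d, s, t, v = design_and_inputs
        p1 = emit_design_report(d, tmp_path / "a", s, t, v)
        p2 = emit_design_report(d, tmp_path / "b", s, t, v)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
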