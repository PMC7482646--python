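import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthpanel as gp
from growthpanel.filtering import (
    RARE_MAF,
    compute_maf,
    deleterious_vote,
    inheritance_fit,
    lookup_known_mutation,
    select_qualifying_variants,
)
from growthpanel.io import default_known_mutations
from growthpanel.records import MISSING, PredictionProfile, VariantRecord
from growthpanel.simulate import CohortSimConfig, DiagnosticSpike, simulate_cohort
from growthpanel.simulate import known_table_from_truth
from tests.conftest import make_matrix


class TestComputeMaf:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 2], 0.0),  # fixed for alt: minor allele is ref
            ([0, 1, 1, 0, MISSING], 2 / 8),  # 2 alt alleles over 4 called samples
            ([1, 1, 1, 1], 0.5),
        ],
    )
    def test_against_hand_enumeration(self, column, expected):
        assert compute_maf(np.array(column)) == pytest.approx(expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_maf(np.array([MISSING, MISSING]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=30))
    def test_matches_bruteforce_allele_count(self, column):
        col = np.array(column)
        obs = [c for c in column if c != MISSING]
        if not obs:
            with pytest.raises(ValueError):
                compute_maf(col)
            return
        alt = sum(obs) / (2 * len(obs))
        assert compute_maf(col) == pytest.approx(min(alt, 1 - alt))


class TestDeleteriousVote:
    @pytest.mark.parametrize(
        "n_del,n_tol,n_missing,votes,supporting",
        [
            (5, 5, 0, 5, True),   # boundary: exactly 5 deleterious
            (4, 0, 6, 4, False),  # missing calls do not count as deleterious
            (10, 0, 0, 10, True),
            (0, 10, 0, 0, False),
        ],
    )
    def test_vote_boundaries(self, n_del, n_tol, n_missing, votes, supporting):
        calls = ("D",) * n_del + ("T",) * n_tol + (None,) * n_missing
        assert deleterious_vote(PredictionProfile(calls)) == (votes, supporting)


class TestInheritanceFit:
    @pytest.mark.parametrize(
        "zygos,mode,sexes,expected",
        [
            (["het"], "AD", ["male"], True),
            (["het"], "AR", ["female"], False),  # single het never fits AR
            (["het", "hom"], "AR", ["female", "male"], True),
            (["hemi"], "XL", ["male"], True),
            (["het"], "XL", ["female"], False),
            (["hom"], "XL", ["female"], True),
        ],
    )
    def test_mode_rules(self, zygos, mode, sexes, expected):
        assert inheritance_fit(zygos, mode, sexes) is expected

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            inheritance_fit(["het"], "mitochondrial")


class TestKnownLookup:
    def test_published_acan_nonsense_is_known(self):
        table = default_known_mutations()
        m = lookup_known_mutation("ACAN", "c.2023C > T(ENST_00000439576)", table)
        assert m is not None and m.classification == "Pathogenic"

    def test_absent_variant_no_match(self):
        table = default_known_mutations()
        assert lookup_known_mutation("ACAN", "c.1G > A", table) is None

    def test_same_hgvs_different_gene_no_match(self):
        table = default_known_mutations()
        assert lookup_known_mutation("GH1", "c.2023C > T(ENST_00000439576)", table) is None


def _variant(vid="v0", gene="ACAN", csq="nonsense", maf=0.001, chrom="1", preds=None):
    return VariantRecord(
        variant_id=vid, gene=gene, chrom=chrom, pos=100, ref="C", alt="T",
        consequence=csq, annotation_maf=maf,
        predictions=preds or PredictionProfile(),
    )


class TestQualifyingSelection:
    def test_case_only_rare_nonsense_retained(self, small_panel):
        m = make_matrix([[1], [0], [0], [0]], group=["case", "case", "control", "control"])
        qvs = select_qualifying_variants([_variant()], m, small_panel)
        assert len(qvs) == 1 and qvs[0].record.variant_id == "v0"

    def test_control_carrier_excluded(self, small_panel):
        m = make_matrix([[1], [0], [1], [0]], group=["case", "case", "control", "control"])
        assert select_qualifying_variants([_variant()], m, small_panel) == []

    def test_maf_exactly_two_percent_excluded(self, small_panel):
        m = make_matrix([[1], [0], [0], [0]], group=["case", "case", "control", "control"])
        v = _variant(maf=0.02)
        assert select_qualifying_variants([v], m, small_panel) == []

    def test_synonymous_excluded(self, small_panel):
        m = make_matrix([[1], [0], [0], [0]], group=["case", "case", "control", "control"])
        assert select_qualifying_variants([_variant(csq="synonymous")], m, small_panel) == []

    def test_missense_requires_supporting_vote(self, small_panel):
        m = make_matrix([[1], [0], [0], [0]], group=["case", "case", "control", "control"])
        weak = _variant(csq="missense", preds=PredictionProfile(("D",) * 4 + ("T",) * 6))
        strong = _variant(csq="missense", preds=PredictionProfile(("D",) * 5 + ("T",) * 5))
        assert select_qualifying_variants([weak], m, small_panel) == []
        assert len(select_qualifying_variants([strong], m, small_panel)) == 1

    def test_gene_absent_from_panel_errors(self, small_panel):
        m = make_matrix([[1], [0]], group=["case", "control"])
        with pytest.raises(ValueError, match="absent from panel"):
            select_qualifying_variants([_variant(gene="NOT_A_GENE")], m, small_panel)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        case_doses=st.lists(st.sampled_from([0, 1, 2]), min_size=2, max_size=8),
        control_row=st.integers(min_value=0, max_value=7),
    )
    def test_adding_a_control_carrier_only_removes_variants(
        self, small_panel, case_doses, control_row
    ):
        """Monotonicity of the cascade: giving a control a variant allele can
        only shrink the qualifying set."""
        n_ctrl = 8
        doses = [[d] for d in case_doses] + [[0]] * n_ctrl
        groups = ["case"] * len(case_doses) + ["control"] * n_ctrl
        m = make_matrix(doses, group=groups)
        before = select_qualifying_variants([_variant()], m, small_panel)
        doses2 = [r[:] for r in doses]
        doses2[len(case_doses) + control_row % n_ctrl][0] = 1
        m2 = make_matrix(doses2, group=groups)
        after = select_qualifying_variants([_variant()], m2, small_panel)
        assert {q.record.variant_id for q in after} <= {
            q.record.variant_id for q in before
        }


class TestSpikeRecovery:
    def test_spiked_diagnostics_are_fully_recovered(self, panel):
        """Every spiked case-only qualifying variant appears in the
        qualifying set, and no common variant ever does."""
        spikes = [
            DiagnosticSpike(gene="ACAN", consequence="nonsense", carrier_index=0,
                            known_mutation=True),
            DiagnosticSpike(gene="GH1", consequence="missense", carrier_index=5,
                            known_mutation=True),
            DiagnosticSpike(gene="CUL7", consequence="nonsense", inheritance="AR",
                            zygosity="hom", carrier_index=9),
        ]
        c = simulate_cohort(CohortSimConfig(panel=panel, seed=31, spikes=spikes))
        qvs = select_qualifying_variants(
            c.variants, c.genotypes, panel, known_table_from_truth(c.truth)
        )
        got = {q.record.variant_id for q in qvs}
        for s in c.truth.spikes:
            assert s.variant_id in got
        by_id = {v.variant_id: v for v in c.variants}
        for q in qvs:
            maf = by_id[q.record.variant_id].annotation_maf
            assert maf is None or maf < RARE_MAF
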