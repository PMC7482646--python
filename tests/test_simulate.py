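import numpy as np
import pytest

import growthpanel as gp
from growthpanel.burden import carriage_table
from growthpanel.records import MISSING
from growthpanel.simulate import (
    CohortSimConfig,
    DiagnosticSpike,
    PhenotypeEffect,
    simulate_cohort,
    simulate_phenotypes,
    spike_diagnostic_variants,
)


def _by_gene(variants):
    out = {}
    for v in variants:
        out.setdefault(v.gene, []).append(v)
    return out


class TestDeterminismAndMoments:
    def test_same_seed_same_cohort(self, small_panel):
        cfg = dict(panel=small_panel, n_cases=20, n_controls=20, seed=9)
        a = simulate_cohort(CohortSimConfig(**cfg))
        b = simulate_cohort(CohortSimConfig(**cfg))
        assert a.genotypes == b.genotypes
        assert a.phenotypes.frame.equals(b.phenotypes.frame)

    def test_standing_height_mean_matches_configured_moment(self, panel):
        """Cohort mean standing height SDS lands within 3 SEs of -2.9."""
        c = simulate_cohort(CohortSimConfig(panel=panel, seed=12))
        h = c.phenotypes.frame["standing_height_sds"]
        se = 0.7 / np.sqrt(len(h))
        assert abs(h.mean() - (-2.9)) < 3 * se

    def test_sex_ratio_near_61_percent_male(self, panel):
        c = simulate_cohort(CohortSimConfig(panel=panel, seed=4))
        frac = (c.genotypes.sex == "male").mean()
        assert abs(frac - 0.61) < 0.08


class TestNullCarriage:
    def test_null_odds_ratios_concentrate_around_one(self, panel):
        """With all enrichments at OR=1 and 40 rare variants per gene, the
        empirical per-gene carriage odds ratio (Haldane-corrected) stays in
        [0.5, 2] for at least 95% of genes."""
        cfg = CohortSimConfig(
            panel=panel,
            seed=7,
            variants_per_gene={g: 40 for g in panel.genes},
            rare_only_genes=frozenset(panel.genes),
        )
        c = simulate_cohort(cfg)
        by_gene = _by_gene(c.variants)
        ors = []
        for g in panel.genes:
            t = carriage_table(g, by_gene[g], c.genotypes, "all")
            ors.append(
                ((t.case_carriers + 0.5) * (t.control_noncarriers + 0.5))
                / ((t.case_noncarriers + 0.5) * (t.control_carriers + 0.5))
            )
        ors = np.asarray(ors)
        assert ((ors >= 0.5) & (ors <= 2.0)).mean() >= 0.95

    def test_enrichment_shifts_case_carriage(self, panel):
        cfg = CohortSimConfig(
            panel=panel,
            seed=21,
            enrichment={"PEX2": 6.0},
            variants_per_gene={"PEX2": 40},
            rare_only_genes=frozenset({"PEX2"}),
        )
        c = simulate_cohort(cfg)
        t = carriage_table("PEX2", _by_gene(c.variants)["PEX2"], c.genotypes, "all")
        assert t.case_rate > t.control_rate + 0.15

    def test_unachievable_enrichment_errors(self, small_panel):
        cfg = CohortSimConfig(
            panel=small_panel,
            n_cases=5,
            n_controls=5,
            seed=1,
            enrichment={"PEX2": 8.0},
            variants_per_gene={"PEX2": 1},
            rare_maf_range=(1e-6, 2e-6),
            rare_only_genes=frozenset({"PEX2"}),
        )
        with pytest.raises(ValueError, match="unachievable"):
            simulate_cohort(cfg)


class TestSpikes:
    def test_spike_present_in_named_case_only(self, small_panel):
        cfg = CohortSimConfig(
            panel=small_panel,
            n_cases=12,
            n_controls=12,
            seed=5,
            spikes=[DiagnosticSpike(gene="ACAN", carrier_index=3)],
        )
        c = simulate_cohort(cfg)
        spike = c.truth.spikes[0]
        col = c.genotypes.column(spike.variant_id)
        carriers = np.where(col > 0)[0]
        assert list(carriers) == [c.genotypes.sample_index(spike.sample_id)]
        assert c.genotypes.group[carriers[0]] == "case"

    def test_ar_spike_is_homozygous(self, small_panel):
        cfg = CohortSimConfig(
            panel=small_panel,
            n_cases=6,
            n_controls=6,
            seed=5,
            spikes=[DiagnosticSpike(gene="CUL7", inheritance="AR", zygosity="hom")],
        )
        c = simulate_cohort(cfg)
        col = c.genotypes.column(c.truth.spikes[0].variant_id)
        assert col.max() == 2

    def test_ar_spike_with_het_zygosity_errors(self):
        with pytest.raises(ValueError, match="homozygous"):
            DiagnosticSpike(gene="CUL7", inheritance="AR", zygosity="het").validate()

    def test_zero_spikes_leaves_cohort_unchanged(self, small_panel):
        a = simulate_cohort(CohortSimConfig(panel=small_panel, n_cases=6, n_controls=6, seed=2))
        m, v, t = spike_diagnostic_variants(a.genotypes, list(a.variants), [], small_panel)
        assert m == a.genotypes and len(v) == len(a.variants) and t == []

    def test_spike_id_collision_errors(self, small_panel):
        a = simulate_cohort(CohortSimConfig(panel=small_panel, n_cases=6, n_controls=6, seed=2))
        with pytest.raises(ValueError, match="collides"):
            spike_diagnostic_variants(
                a.genotypes,
                list(a.variants),
                [DiagnosticSpike(gene="ACAN", variant_id=a.variants[0].variant_id)],
                small_panel,
            )


class TestPhenotypeModel:
    def test_zero_betas_leave_phenotypes_uncorrelated(self, panel):
        """With no genetic effects, |r| between any common variant's dosage
        and standing height stays below 0.2 for 99% of variants at n=526."""
        c = simulate_cohort(
            CohortSimConfig(panel=panel, seed=17, phenotype_controls=True, missing_rate=0.0)
        )
        y = c.phenotypes.frame["standing_height_sds"].to_numpy()
        d = c.genotypes.dosages.astype(float)
        sd = d.std(axis=0)
        use = sd > 0
        dc = (d[:, use] - d[:, use].mean(axis=0)) / sd[use]
        yc = (y - y.mean()) / y.std()
        r = np.abs(dc.T @ yc) / len(y)
        assert (r < 0.2).mean() >= 0.99

    def test_spiked_beta_recovered_within_3_se(self, panel):
        base = CohortSimConfig(panel=panel, seed=23, phenotype_controls=True)
        c0 = simulate_cohort(base)
        # pick a common variant, then rerun the identical cohort with an effect
        mafs = [(v.variant_id, v.annotation_maf) for v in c0.variants]
        vid = next(v for v, m in mafs if m is not None and m > 0.2)
        cfg = CohortSimConfig(
            panel=panel, seed=23, phenotype_controls=True,
            effects=[PhenotypeEffect(vid, "standing_height_sds", -0.5)],
        )
        c = simulate_cohort(cfg)
        res = gp.linear_regression(
            c.phenotypes.frame["standing_height_sds"].to_numpy(),
            c.genotypes.column(vid).astype(float),
            variant_id=vid,
        )
        assert abs(res.beta - (-0.5)) < 3 * res.se

    def test_noise_free_single_effect_is_affine_in_dosage(self, small_panel):
        cfg = CohortSimConfig(
            panel=small_panel, n_cases=15, n_controls=15, seed=3,
            phenotype_controls=True, missing_rate=0.0, noise_free_phenotypes=True,
        )
        c0 = simulate_cohort(cfg)
        vid = c0.genotypes.variant_ids[0]
        cfg2 = CohortSimConfig(
            panel=small_panel, n_cases=15, n_controls=15, seed=3,
            phenotype_controls=True, missing_rate=0.0, noise_free_phenotypes=True,
            effects=[PhenotypeEffect(vid, "als", 2.0)],
        )
        c = simulate_cohort(cfg2)
        d = c.genotypes.column(vid).astype(float)
        y = c.phenotypes.frame["als"].to_numpy()
        np.testing.assert_allclose(y, np.clip(10.0 + 2.0 * d, 0.5, None), atol=1e-3)
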