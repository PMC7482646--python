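"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
candidate-gene resequencing panel over a cohort of short-stature cases and
ethnically matched adult controls. Per gene, a configurable number of
variants is drawn with a right-skewed minor-allele-frequency spectrum
(default 80% rare, MAF < 2%); genotypes follow Hardy-Weinberg proportions
at the drawn MAF. Case carriage can be enriched or depleted per gene to a
configured carriage odds ratio (enrichment acts on carrier status, not
allele counts, because the downstream burden test is carriage-collapsing).
Diagnostic variants with defined inheritance modes can be spiked into
named case samples, and phenotypes are generated from a linear
dosage-effect model on top of the cohort's published baseline moments.

Controls receive genotypes only by default (they were anonymized adults
with no phenotype data); phenotype generation for controls can be enabled
for calibration experiments.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``config.seed``, so a fixed seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    MISSING,
    GenotypeMatrix,
    PanelDefinition,
    PhenotypeTable,
    PredictionProfile,
    VariantRecord,
)

_BASES = ("A", "C", "G", "T")

#: Default phenotype means/SDs. SDS phenotypes use the cohort's published
#: baseline moments where printed; head circumference, IGF-1, IGFBP-3 and
#: ALS moments are chosen to match the published prevalence statements
#: (42% microcephalic, ~53% IGF-1 deficient) and assay ranges.
DEFAULT_PHENOTYPE_MODEL: Dict[str, Tuple[float, float]] = {
    "standing_height_sds": (-2.9, 0.7),
    "sitting_height_sds": (-2.2, 2.4),
    "birthweight_sds": (-0.7, 1.2),
    "birth_length_sds": (-0.7, 1.3),
    "target_height_sds": (-1.3, 0.8),
    "head_circumference_sds": (-1.7, 1.3),
    "igf1_sds": (-2.0, 1.0),
    "igfbp3_sds": (-1.5, 1.0),
    "als": (10.0, 3.0),
}


@dataclass(frozen=True)
class DiagnosticSpike:
    """A truth-labelled diagnostic variant to insert into one case sample.

    ``carrier_index`` indexes into the case side of the cohort. Zygosity
    must be consistent with the inheritance mode: AR spikes are homozygous,
    XL spikes hemizygous (male carrier); AD spikes are het (or hom).
    """

    gene: str
    consequence: str = "nonsense"
    inheritance: str = "AD"
    carrier_index: int = 0
    zygosity: str = "het"
    predictions: PredictionProfile = field(
        default_factory=lambda: PredictionProfile.uniform("D")
    )
    known_mutation: bool = False
    variant_id: Optional[str] = None
    hgvs_c: Optional[str] = None

    def validate(self) -> None:
        if self.inheritance == "AR" and self.zygosity != "hom":
            raise ValueError(
                f"AR spike in {self.gene} must be homozygous, got {self.zygosity!r}"
            )
        if self.inheritance == "XL" and self.zygosity not in ("hemi", "hom"):
            raise ValueError(
                f"XL spike in {self.gene} must be hemizygous (or hom female), "
                f"got {self.zygosity!r}"
            )
        if self.inheritance == "AD" and self.zygosity not in ("het", "hom"):
            raise ValueError(f"AD spike zygosity {self.zygosity!r} invalid")


@dataclass(frozen=True)
class PhenotypeEffect:
    """A per-allele additive effect of one variant on one phenotype."""

    variant_id: str
    phenotype: str
    beta: float


@dataclass
class CohortSimConfig:
    """Study conditions for the simulated cohort.

    Defaults reproduce the cohort the analysis was designed for: 263 cases
    and 263 controls, 61% male, a 232-gene panel, ~8 variants per gene with
    an 80/20 rare/common MAF split, 2% genotype missingness, and the
    published phenotype moments.
    """

    panel: PanelDefinition
    n_cases: int = 263
    n_controls: int = 263
    mean_variants_per_gene: float = 8.0
    variants_per_gene: Dict[str, int] = field(default_factory=dict)
    prop_rare: float = 0.8
    rare_maf_range: Tuple[float, float] = (5e-4, 0.02)
    common_maf_range: Tuple[float, float] = (0.02, 0.5)
    rare_only_genes: frozenset = frozenset()
    enrichment: Dict[str, float] = field(default_factory=dict)
    spikes: List[DiagnosticSpike] = field(default_factory=list)
    missing_rate: float = 0.02
    phenotype_model: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MODEL)
    )
    effects: List[PhenotypeEffect] = field(default_factory=list)
    phenotype_controls: bool = False
    noise_free_phenotypes: bool = False
    sex_ratio_male: float = 0.61
    mean_age: float = 8.4
    sd_age: float = 3.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for g, odds in self.enrichment.items():
            if odds <= 0:
                raise ValueError(f"enrichment odds ratio for {g} must be > 0")
            if g not in self.panel:
                raise ValueError(f"enrichment gene {g} not in panel")
        for s in self.spikes:
            s.validate()
            if s.gene not in self.panel:
                raise ValueError(f"spike gene {s.gene} not in panel")
            if not (0 <= s.carrier_index < self.n_cases):
                raise ValueError("spike carrier_index must address a case sample")


@dataclass
class SpikeTruth:
    variant_id: str
    gene: str
    sample_id: str
    zygosity: str
    consequence: str
    inheritance: str
    known_mutation: bool
    hgvs_c: str


@dataclass
class TruthLog:
    """Ground truth of everything the simulator planted."""

    spikes: List[SpikeTruth] = field(default_factory=list)
    enrichment: Dict[str, float] = field(default_factory=dict)
    effects: List[PhenotypeEffect] = field(default_factory=list)


class SimulatedCohort(NamedTuple):
    genotypes: GenotypeMatrix
    variants: List[VariantRecord]
    phenotypes: PhenotypeTable
    truth: TruthLog


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _gene_chrom(panel: PanelDefinition, gene: str, idx: int) -> str:
    if panel.inheritance(gene) == "XL":
        return "X"
    return str(1 + idx % 22)


def _draw_variants(rng: np.random.Generator, config: CohortSimConfig):
    """Draw variant records and their true MAFs for every panel gene."""
    variants: List[VariantRecord] = []
    mafs: List[float] = []
    csq_names = ("missense", "synonymous", "nonsense", "frameshift", "other")
    csq_probs = (0.50, 0.30, 0.05, 0.05, 0.10)
    lo_r, hi_r = np.log10(config.rare_maf_range[0]), np.log10(config.rare_maf_range[1])
    for idx, gene in enumerate(config.panel.genes):
        n_var = config.variants_per_gene.get(gene)
        if n_var is None:
            n_var = 1 + rng.poisson(max(config.mean_variants_per_gene - 1.0, 0.0))
        chrom = _gene_chrom(config.panel, gene, idx)
        base = 1_000_000 * (idx + 1)
        for j in range(int(n_var)):
            rare = (
                True
                if gene in config.rare_only_genes
                else bool(rng.random() < config.prop_rare)
            )
            if rare:
                maf = float(10 ** rng.uniform(lo_r, hi_r))
            else:
                maf = float(rng.uniform(*config.common_maf_range))
            csq = str(rng.choice(csq_names, p=csq_probs))
            ref = str(rng.choice(_BASES))
            if csq == "frameshift":
                alt = ref + str(rng.choice(_BASES))  # 1-bp insertion
            else:
                alt = str(rng.choice([b for b in _BASES if b != ref]))
            if csq in ("missense", "nonsense"):
                damaging = rng.random() < 0.25
                p_del = 0.85 if damaging else 0.10
                calls = []
                for _ in range(10):
                    if rng.random() < 0.05:
                        calls.append(None)
                    else:
                        calls.append("D" if rng.random() < p_del else "T")
                profile = PredictionProfile(tuple(calls))
            else:
                profile = PredictionProfile()
            variants.append(
                VariantRecord(
                    variant_id=f"{gene}_v{j}",
                    gene=gene,
                    chrom=chrom,
                    pos=base + 150 * j,
                    ref=ref,
                    alt=alt,
                    consequence=csq,
                    annotation_maf=maf,
                    predictions=profile,
                )
            )
            mafs.append(maf)
    return variants, np.asarray(mafs)


def _draw_genotypes(rng, mafs, on_x, male) -> np.ndarray:
    """Hardy-Weinberg genotypes; male X drawn haploid and coded 0/2."""
    n, m = len(male), len(mafs)
    dose = rng.binomial(2, np.broadcast_to(mafs, (n, m)))
    if on_x.any() and male.any():
        hemi = rng.binomial(1, np.broadcast_to(mafs[on_x], (int(male.sum()), int(on_x.sum()))))
        dose[np.ix_(male, on_x)] = 2 * hemi
    return dose.astype(np.int8)


def _apply_enrichment(rng, dose_cases, cols, q, odds_ratio, gene, n_cases):
    """Resample case carrier status at a gene to hit a carriage odds ratio."""
    p0 = 1.0 - float(np.prod((1.0 - q) ** 2))
    if p0 <= 0.0:
        raise ValueError(
            f"enrichment at {gene} unachievable: baseline carriage probability is 0 "
            "(increase the variant count or sample size)"
        )
    if p0 >= 1.0 and odds_ratio < 1.0:
        raise ValueError(
            f"enrichment at {gene} unachievable: baseline carriage probability is 1"
        )
    odds1 = odds_ratio * p0 / (1.0 - p0) if p0 < 1.0 else np.inf
    p1 = odds1 / (1.0 + odds1) if np.isfinite(odds1) else 1.0
    if p1 * n_cases < 1.0 and odds_ratio > 1.0:
        raise ValueError(
            f"enrichment at {gene} unachievable at this MAF and n "
            "(expected carrier count < 1; increase n_cases)"
        )
    target = rng.random(n_cases) < p1
    block = dose_cases[:, cols]
    carrier = (block > 0).any(axis=1)
    # demote excess carriers
    for i in np.where(carrier & ~target)[0]:
        block[i, :] = 0
    # promote non-carriers: force one variant het, chosen proportional to MAF
    promote = np.where(target & ~carrier)[0]
    if promote.size:
        w = q / q.sum()
        picks = rng.choice(len(cols), size=promote.size, p=w)
        for i, j in zip(promote, picks):
            block[i, j] = 1
    dose_cases[:, cols] = block


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: Sequence[PhenotypeEffect],
    config: CohortSimConfig,
    rng: Optional[np.random.Generator] = None,
    sample_ids: Optional[Sequence[str]] = None,
    ages: Optional[np.ndarray] = None,
) -> PhenotypeTable:
    """Generate phenotypes as mean + sum(beta * dosage) + Gaussian noise.

    SDS phenotypes are already age- and sex-standardized, so no default
    age/sex trend is added; missing dosages contribute 0.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ids = list(sample_ids) if sample_ids is not None else list(genotypes.sample_ids)
    rows = [genotypes.sample_index(s) for s in ids]
    n = len(ids)
    if ages is None:
        ages = np.clip(rng.normal(config.mean_age, config.sd_age, n), 2.0, None)
    sex = [genotypes.sex[i] for i in rows]
    frame = pd.DataFrame({"sample_id": ids, "sex": sex, "age_years": np.round(ages, 2)})
    dose = genotypes.dosages[rows, :].astype(float)
    dose[dose == MISSING] = 0.0
    for name, (mean, sd) in config.phenotype_model.items():
        vals = np.full(n, float(mean))
        if not config.noise_free_phenotypes:
            vals = vals + rng.normal(0.0, sd, n)
        for eff in effects:
            if eff.phenotype == name:
                vals = vals + eff.beta * dose[:, genotypes.variant_index(eff.variant_id)]
        if name == "als":
            vals = np.clip(vals, 0.5, None)
        frame[name] = np.round(vals, 4)
    return PhenotypeTable(frame)


def spike_diagnostic_variants(
    genotypes: GenotypeMatrix,
    variants: List[VariantRecord],
    specs: Sequence[DiagnosticSpike],
    panel: PanelDefinition,
) -> Tuple[GenotypeMatrix, List[VariantRecord], List[SpikeTruth]]:
    """Insert diagnostic spike variants, each carried by exactly one case.

    Returns a new matrix/variant list plus the truth records. AR spikes are
    homozygous, XL spikes hemizygous in males (dosage 2 on X); spiked
    variants are absent from every control.
    """
    if not specs:
        return genotypes, variants, []
    existing = set(v.variant_id for v in variants)
    case_ids = [s for s, g in zip(genotypes.sample_ids, genotypes.group) if g == "case"]
    new_cols = []
    new_records = []
    truths = []
    for k, spec in enumerate(specs):
        spec.validate()
        if spec.gene not in panel:
            raise ValueError(f"spike gene {spec.gene} not in panel")
        vid = spec.variant_id or f"{spec.gene}_spike{k}"
        if vid in existing:
            raise ValueError(f"spike variant id {vid} collides with an existing variant")
        existing.add(vid)
        sample_id = case_ids[spec.carrier_index]
        row = genotypes.sample_index(sample_id)
        chrom = "X" if spec.inheritance == "XL" else _gene_chrom(
            panel, spec.gene, list(panel.genes).index(spec.gene)
        )
        if spec.inheritance == "XL" and spec.zygosity == "hemi":
            if genotypes.sex[row] != "male":
                raise ValueError(
                    f"hemizygous XL spike requires a male carrier; {sample_id} is "
                    f"{genotypes.sex[row]}"
                )
        dose = {"het": 1, "hom": 2, "hemi": 2}[spec.zygosity]
        col = np.zeros(genotypes.n_samples, dtype=np.int8)
        col[row] = dose
        new_cols.append(col)
        hgvs = spec.hgvs_c or f"c.{100 + 7 * k}G > T"
        csq = spec.consequence
        new_records.append(
            VariantRecord(
                variant_id=vid,
                gene=spec.gene,
                chrom=chrom,
                pos=999_000_000 + k,
                ref="G",
                alt="GT" if csq == "frameshift" else "T",
                consequence=csq,
                annotation_maf=5e-4,
                predictions=spec.predictions,
                hgvs_c=hgvs,
            )
        )
        truths.append(
            SpikeTruth(
                variant_id=vid,
                gene=spec.gene,
                sample_id=sample_id,
                zygosity=spec.zygosity,
                consequence=csq,
                inheritance=spec.inheritance,
                known_mutation=spec.known_mutation,
                hgvs_c=hgvs,
            )
        )
    dosages = np.column_stack([genotypes.dosages] + new_cols)
    matrix = GenotypeMatrix(
        dosages,
        genotypes.sample_ids,
        list(genotypes.variant_ids) + [r.variant_id for r in new_records],
        genotypes.group,
        genotypes.sex,
    )
    return matrix, variants + new_records, truths


def known_table_from_truth(truth: TruthLog) -> pd.DataFrame:
    """Known-mutation table covering the spikes flagged as known."""
    rows = [
        {"gene": s.gene, "hgvs_c": s.hgvs_c, "classification": "Pathogenic",
         "source": "truth"}
        for s in truth.spikes
        if s.known_mutation
    ]
    return pd.DataFrame(rows, columns=["gene", "hgvs_c", "classification", "source"])


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Generate a full case-control cohort under the configured conditions.

    Order of operations: draw variants and MAFs; draw Hardy-Weinberg
    genotypes; resample case carriage for enriched genes; generate
    phenotypes from true dosages; apply genotype missingness; insert
    diagnostic spikes last (so spikes are never masked).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"case{i:04d}" for i in range(config.n_cases)] + [
        f"ctrl{i:04d}" for i in range(config.n_controls)
    ]
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls, dtype=object)
    sex = np.where(rng.random(n) < config.sex_ratio_male, "male", "female").astype(object)

    variants, mafs = _draw_variants(rng, config)
    on_x = np.asarray([v.chrom == "X" for v in variants])
    male = np.asarray(sex == "male")
    dosages = _draw_genotypes(rng, mafs, on_x, male)

    truth = TruthLog(enrichment=dict(config.enrichment), effects=list(config.effects))

    col_of = {v.variant_id: j for j, v in enumerate(variants)}
    case_block = dosages[: config.n_cases, :]
    for gene, odds in config.enrichment.items():
        if odds == 1.0:
            continue
        cols = np.asarray([col_of[v.variant_id] for v in variants if v.gene == gene])
        if cols.size == 0:
            raise ValueError(f"enrichment gene {gene} drew no variants")
        _apply_enrichment(
            rng, case_block, cols, mafs[cols], odds, gene, config.n_cases
        )
    dosages[: config.n_cases, :] = case_block

    matrix = GenotypeMatrix(dosages, sample_ids, [v.variant_id for v in variants], group, sex)

    pheno_ids = (
        list(sample_ids) if config.phenotype_controls else sample_ids[: config.n_cases]
    )
    phenotypes = simulate_phenotypes(
        matrix, config.effects, config, rng=rng, sample_ids=pheno_ids
    )

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING
        matrix = GenotypeMatrix(
            dosages, sample_ids, [v.variant_id for v in variants], group, sex
        )

    matrix, variants, spike_truths = spike_diagnostic_variants(
        matrix, variants, config.spikes, config.panel
    )
    truth.spikes = spike_truths
    return SimulatedCohort(matrix, variants, phenotypes, truth)
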