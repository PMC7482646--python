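# Methods

## Problem setting

The package analyses a candidate-gene resequencing panel for short
stature of undefined aetiology (SS-UA): prepubertal children with height
SDS ≤ −2.5, a normal growth-hormone response, and no identified cause,
sequenced over 232 growth-related genes alongside ethnically matched
anonymized adult controls. Three complementary analyses run on the same
genotype matrix: a diagnostic filter-and-classify chain on rare
case-only variants, per-gene carriage burden tests, and per-variant
phenotype association, followed by cross-method overlap logic.

## Data model

Genotypes are alt-allele dosages 0/1/2 with −1 for missing; matrices are
samples × variants with case/control and sex labels held in a sidecar
(cases and controls were separate cohorts, so labels do not travel in
the VCF). Coordinates are 1-based inclusive, as in VCF. Hemizygous male
X genotypes are coded 0 or 2 (alt count doubled): carriage, MAF and
additive-dosage logic then work identically on all chromosomes, while
zygosity helpers recover hemizygosity from chromosome and sex for the
inheritance-fit check. Multi-allelic VCF sites are split into biallelic
records; the split conserves total alt dosage per sample.

## Diagnostic filter cascade and classification

A variant qualifies when it is (a) carried by ≥ 1 case and 0 controls,
(b) exonic (missense / nonsense / frameshift; synonymous and
non-coding classes are excluded), (c) rare — MAF strictly < 2%, using
the annotation MAF when present, else the cohort MAF (the source
precedence is a package choice; both are recorded), and (d) consistent
with the gene's inheritance mode: AD accepts any carrier, AR requires a
homozygote (compound heterozygotes are not accepted — no phasing is
available; a documented limitation), XL requires a hemizygous male or
homozygous female. Missense variants must additionally be called
deleterious by ≥ 5 of the 10 prediction algorithms; missing predictor
calls count as non-deleterious, the conservative reading of a
positive-call vote.

Qualifying variants receive the four automatically justifiable ACMG/AMP
evidence codes: PVS1 (nonsense/frameshift in a gene whose disease
mechanism is loss of function, per the panel's LOF flag), PS1 (exact
gene + HGVS match to a known pathogenic mutation in a local lookup
table that stands in for Ensembl/LOVD), PM2 (case-only and rare), PP3
(the ≥ 5/10 predictor consensus). The combining table ships as TSV and
accepts the full code vocabulary (benign-side codes combine correctly
but are never auto-assigned). One deliberate departure from the strict
Richards 2015 table: PVS1 + one moderate code yields Pathogenic rather
than Likely pathogenic, matching how nonsense variants are called in
this setting; the table is data, so the strict combination can be
swapped in. A missense variant meeting every other criterion but
failing the predictor consensus carries a contradiction flag and is
reported as VUS even when a pathogenic-side rule fires. Indels pass
through as "Unclassifiable (indel)" — the upstream annotations carry
too little information. Diagnostic yield counts distinct patients with
≥ 1 Pathogenic / Likely pathogenic call over the case cohort.

## Carriage burden test

Per gene and variant subset (all / rare MAF < 2% / indel), a sample is
a carrier iff it has ≥ 1 non-missing genotype ≥ 1 at any subset variant;
samples missing at every subset variant are excluded from that gene's
margins (carriage cannot be asserted from no data). The 2×2 table is
tested with Pearson's χ², df = 1, no continuity correction (Yates is
available behind a flag). Degenerate tables (no carriers anywhere, or
everyone a carrier) return statistic 0, P = 1, direction none.
Direction is the sign of (case carriage proportion − control
proportion). Correction is over the m = 232 genes tested: Bonferroni by
default for the all-variant scan, Benjamini–Hochberg for the
rare-variant scan; both are exposed because the two conventions are in
genuine use for the respective scans.

## Genotype QC and association

QC order: sample call rate ≥ 75% → variant call rate ≥ 75% →
heterozygosity outliers (|het rate − mean| ≥ 3 SD; no removals when
SD = 0) → exact Hardy–Weinberg test P ≤ 10⁻⁴ removed → greedy windowed
LD pruning (window 50 variants, step 5, r² > 0.5 drops the lower-MAF
member; parameters are package defaults, exposed in config) → common
(MAF > 2%) restriction. Retention at exactly a threshold is non-strict.
The surviving pruned common count is `m_effective`, always computed,
never hard-coded. The Hardy–Weinberg test is the standard two-sided
exact conditional test (no mid-P): given allele counts, heterozygote
counts are hypergeometric under equilibrium and P sums the
probabilities of all heterozygote counts no more probable than the
observed one, evaluated in log-space; on the X chromosome only females
enter the test. Ancestry structure is controlled with principal
components of the standardized, mean-imputed pruned dosage matrix
(signs fixed by making each component's largest-magnitude loading
positive) rather than reference-panel ancestry weighting.

Association regresses each common variant's additive dosage against
each of the nine phenotype columns by OLS with sex, age and 4 PCs as
covariates, complete-case per (variant, phenotype) pair; the dosage
coefficient's two-sided t-test P is reported with two verdicts: strict
(P < α/m_effective) and lenient (P ≤ 0.001). Single-variant additive
tests are used throughout; haplotype-block testing is out of scope.
Constant-dosage pairs are flagged untestable rather than dropped
silently; collinear covariates raise.

## Overlaps

Overlap A = significant(all) ∩ significant(rare). Genes_assoc uses the
lenient rule (raw P ≤ 0.001 for ≥ 1 phenotype) — the strict threshold
is for single-test claims, the lenient one for convergence across
methods. Overlap B = (significant(all) ∪ significant(rare)) ∩
genes_assoc; the triple intersection adds the rare scan.

## Synthetic cohort generator

The generator defines the study conditions: 263 cases / 263 controls
(61% male, age 8.4 ± 3.2 y), ~8 variants per gene (1 + Poisson), an
80/20 rare/common MAF split (rare log-uniform on [5×10⁻⁴, 0.02], common
uniform on [0.02, 0.5]), Hardy–Weinberg genotypes (haploid draws for
male X), 2% genotype missingness, and the cohort's published phenotype
moments — standing height −2.9 (0.7), sitting height −2.2 (2.4),
birthweight −0.7 (1.2), birth length −0.7 (1.3), target height −1.3
(0.8) SDS. Moments not printed were fixed once from the published
prevalence statements: head circumference −1.7 (1.3) SDS (≈ 42%
microcephalic), IGF-1 −2.0 (1.0) SDS (≈ half the cohort IGF-1
deficient), IGFBP-3 −1.5 (1.0) SDS, ALS 10 (3) mg/L truncated at 0.5.
Controls receive genotypes only (they were anonymized adults without
phenotypes); phenotype generation for controls can be switched on for
calibration runs.

Per-gene case enrichment acts at the carriage level, matching the test
statistic: the baseline carriage probability p₀ follows from the drawn
MAFs, the target p₁ from the configured odds ratio, and case carrier
status is resampled to Bernoulli(p₁) (excess carriers zeroed;
promoted non-carriers get one het variant chosen ∝ MAF). Enrichment
that implies an expected carrier count below one raises with a
suggestion to enlarge the cohort. Diagnostic spikes are inserted last
(never masked by missingness), each carried by exactly one case with
zygosity validated against the inheritance mode; phenotype effects are
linear in true dosage with Gaussian noise. All draws flow from one
seeded generator, so a fixed seed reproduces the cohort byte for byte.

What the generator does not emulate: linkage disequilibrium beyond
duplicated-column tests (enough to exercise pruning, not realistic
haplotype structure), ancestry admixture, relatedness, batch effects,
or sequencing error. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery under the assumed
generative model, not robustness to those real-data complications.

## Numerical and design choices

- χ² and OLS are delegated to scipy/statsmodels; the exact HWE test, the
  carriage collapse, the filter cascade, the rule engine, LD pruning and
  the simulator are implemented here. Tests verify each against an
  independent oracle (exact-fraction enumeration for HWE, closed-form
  Σ(O−E)²/E, normal-equations OLS, a step-up BH reimplementation).
- HWE tie handling: probabilities equal to the observed one (within a
  10⁻¹⁰ relative tolerance on floating-point equality) are included in
  the two-sided sum.
- LD pruning recomputes nothing across windows (greedy, deterministic);
  pruning an already-pruned set is a no-op (idempotence is tested).
- Calibration experiments that estimate per-gene carriage odds ratios
  use rare-only genes at 40 variants/gene: with common variants included
  carriage saturates near 1 and the empirical OR degenerates, so the
  informative-carriage regime is the meaningful one for that check. The
  null clean-scan rate is estimated over 400 simulated cohorts (SE ≈ 1%)
  because its expectation, 1 − FWER ≈ 96%, sits close to the 95%
  acceptance bound.
- Problem sizes in the test and acceptance suites (e.g. 400 null
  replicates, 200 power replicates, oracle sweeps to n = 30) were chosen
  to keep each estimate's Monte-Carlo error small relative to the bound
  it is compared against.

## Known limitations

Compound-heterozygote AR fits are not recognised; indels are never
classified; the known-mutation lookup is exact-string (no HGVS
normalisation); the combining table implements only count-based rules;
the association scan fits one variant at a time (no mixed models or
kinship correction). The packaged printed-table fixtures reproduce
their source tables verbatim, including internally inconsistent
protein annotations and two obviously corrupted exponents that were
repaired to make the P-value column numeric (noted in the fixture
provenance).
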