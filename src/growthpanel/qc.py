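"""Pre-association genotype quality control.

Filter order: sample call rate -> variant call rate -> heterozygosity
outliers -> Hardy-Weinberg exact test -> LD pruning -> common-variant
(MAF > 2%) restriction. The surviving, approximately independent common
variant count ``m_effective`` feeds the Bonferroni threshold of the
association scan.

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, heterozygote counts are distributed hypergeometrically
under equilibrium, and the two-sided P-value sums the probabilities of all
heterozygote counts no more probable than the observed one. On the X
chromosome the test uses females only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .records import MISSING, GenotypeMatrix, VariantRecord
from .filtering import compute_maf

CALL_RATE_MIN = 0.75
HWE_P_MIN = 1e-4
HET_SD = 3.0
LD_WINDOW = 50
LD_STEP = 5
LD_R2_MAX = 0.5
COMMON_MAF = 0.02


@dataclass
class QCReport:
    """What QC removed, what survived, and the effective test count."""

    samples_removed: Dict[str, str] = field(default_factory=dict)  # id -> reason
    variants_removed: Dict[str, str] = field(default_factory=dict)
    pruned_out: Tuple[str, ...] = ()
    kept_variants: Tuple[str, ...] = ()  # post-prune, common, analysis-ready
    thresholds: Dict[str, float] = field(default_factory=dict)
    m_effective: int = 0

    def summary_rows(self) -> List[dict]:
        rows = [
            {"item": s, "kind": "sample", "action": "removed", "reason": r}
            for s, r in self.samples_removed.items()
        ]
        rows += [
            {"item": v, "kind": "variant", "action": "removed", "reason": r}
            for v, r in self.variants_removed.items()
        ]
        rows += [
            {"item": v, "kind": "variant", "action": "pruned", "reason": "ld"}
            for v in self.pruned_out
        ]
        return rows


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def call_rate_filter(
    matrix: GenotypeMatrix,
    sample_min: float = CALL_RATE_MIN,
    variant_min: float = CALL_RATE_MIN,
) -> Tuple[GenotypeMatrix, Dict[str, str], Dict[str, str]]:
    """Drop samples, then variants, with non-missing fraction below threshold.

    Retention is non-strict (a call rate exactly at the threshold is kept).
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")
    present = matrix.dosages != MISSING
    sample_rate = present.mean(axis=1)
    keep_s = sample_rate >= sample_min
    removed_samples = {
        s: "call_rate" for s, k in zip(matrix.sample_ids, keep_s) if not k
    }
    if not keep_s.any():
        raise ValueError("no data after QC: every sample failed the call-rate filter")
    kept_ids = [s for s, k in zip(matrix.sample_ids, keep_s) if k]
    m2 = matrix.subset_samples(kept_ids)
    present = m2.dosages != MISSING
    var_rate = present.mean(axis=0)
    keep_v = var_rate >= variant_min
    removed_variants = {
        v: "call_rate" for v, k in zip(m2.variant_ids, keep_v) if not k
    }
    if not keep_v.any():
        raise ValueError("no data after QC: every variant failed the call-rate filter")
    m3 = m2.subset_variants([v for v, k in zip(m2.variant_ids, keep_v) if k])
    return m3, removed_samples, removed_variants


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    ``n_aa``/``n_ab``/``n_bb`` are major-hom, het and minor-hom counts (the
    labelling is symmetric). P is the summed probability of all
    heterozygote counts, conditional on the allele counts, that are no more
    probable than the observed count. Monomorphic sites give P = 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    rare = 2 * min(n_aa, n_bb) + n_ab  # minor allele count
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(het + 1)
            - gammaln(hom_common + 1)
            + het * math.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_ab)]
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(1.0, p))


def genotype_counts(column: np.ndarray) -> Tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts over non-missing genotypes."""
    col = np.asarray(column)
    obs = col[col != MISSING]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def heterozygosity_filter(matrix: GenotypeMatrix, k: float = HET_SD) -> List[str]:
    """Sample ids whose het rate deviates >= k SDs from the cohort mean."""
    if matrix.n_samples < 3:
        raise ValueError("heterozygosity filter needs at least 3 samples")
    present = matrix.dosages != MISSING
    with np.errstate(invalid="ignore"):
        het_rate = (matrix.dosages == 1).sum(axis=1) / present.sum(axis=1)
    het_rate = np.nan_to_num(het_rate, nan=0.0)
    sd = het_rate.std()
    if sd == 0 or not np.isfinite(k):
        return []
    outlier = np.abs(het_rate - het_rate.mean()) >= k * sd
    return [s for s, o in zip(matrix.sample_ids, outlier) if o]


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete samples; a monomorphic column gives 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete samples")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    variants: Optional[Sequence[VariantRecord]] = None,
    window: int = LD_WINDOW,
    step: int = LD_STEP,
    r2_max: float = LD_R2_MAX,
) -> List[str]:
    """Greedy windowed LD pruning; returns the kept variant ids.

    Variants are taken in (chrom, pos) order when records are supplied.
    Within each window the lower-MAF member of any pair with r² above
    ``r2_max`` is dropped; the window then advances by ``step``. No
    retained pair within a window exceeds ``r2_max``.
    """
    ids = list(matrix.variant_ids)
    if variants is not None:
        order = {v.variant_id: (_chrom_key(v.chrom), v.pos) for v in variants}
        ids.sort(key=lambda vid: order[vid])
    mafs = {}
    for vid in ids:
        col = matrix.column(vid)
        obs = col[col != MISSING]
        mafs[vid] = compute_maf(col) if obs.size else 0.0
    dropped: set = set()
    start = 0
    while start < len(ids):
        in_window = [v for v in ids[start : start + window] if v not in dropped]
        if len(in_window) > 1:
            # pairwise-complete correlations for the whole window at once
            block = np.ma.masked_equal(
                np.stack([matrix.column(v) for v in in_window]).astype(float), MISSING
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.asarray(np.ma.corrcoef(block).filled(0.0)) ** 2
            np.fill_diagonal(r2, 0.0)
            changed = True
            while changed:
                changed = False
                for i in range(len(in_window)):
                    for j in range(i + 1, len(in_window)):
                        if r2[i, j] > r2_max:
                            a, b = in_window[i], in_window[j]
                            victim_idx = i if mafs[a] <= mafs[b] else j
                            dropped.add(in_window[victim_idx])
                            in_window.pop(victim_idx)
                            r2 = np.delete(
                                np.delete(r2, victim_idx, axis=0), victim_idx, axis=1
                            )
                            changed = True
                            break
                    if changed:
                        break
        if start + window >= len(ids):
            break
        start += step
    return [v for v in ids if v not in dropped]


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def pca_covariates(matrix: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Principal-component scores of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant; constant columns drop
    out. Scores are ordered by variance explained, with each component's
    sign fixed so its largest-magnitude loading is positive. Returns an
    (n_samples, k) array aligned with ``matrix.sample_ids``.
    """
    if k == 0:
        return np.zeros((matrix.n_samples, 0))
    X = matrix.to_float()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    rank = min(X.shape)
    if k > rank:
        raise ValueError(f"K={k} exceeds the rank ({rank}) of the dosage matrix")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

def run_qc(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    sample_call_rate: float = CALL_RATE_MIN,
    variant_call_rate: float = CALL_RATE_MIN,
    het_sd: float = HET_SD,
    hwe_p_min: float = HWE_P_MIN,
    ld_window: int = LD_WINDOW,
    ld_step: int = LD_STEP,
    ld_r2_max: float = LD_R2_MAX,
    common_maf: float = COMMON_MAF,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Run the full QC cascade and compute ``m_effective``.

    Returns the matrix after sample/variant removals (all retained variants,
    not just the pruned common set) plus the report; the analysis-ready
    common set is ``report.kept_variants``.
    """
    by_id = {v.variant_id: v for v in variants}
    report = QCReport(
        thresholds={
            "sample_call_rate": sample_call_rate,
            "variant_call_rate": variant_call_rate,
            "het_sd": het_sd,
            "hwe_p_min": hwe_p_min,
            "ld_window": ld_window,
            "ld_step": ld_step,
            "ld_r2_max": ld_r2_max,
            "common_maf": common_maf,
        }
    )
    m, rs, rv = call_rate_filter(matrix, sample_call_rate, variant_call_rate)
    report.samples_removed.update(rs)
    report.variants_removed.update(rv)

    if m.n_samples >= 3:
        for s in heterozygosity_filter(m, het_sd):
            report.samples_removed[s] = "heterozygosity"
        keep = [s for s in m.sample_ids if s not in report.samples_removed]
        if not keep:
            raise ValueError("no data after QC: heterozygosity filter removed all samples")
        m = m.subset_samples(keep)

    female = m.sex == "female"
    hwe_fail = []
    for vid in m.variant_ids:
        col = m.column(vid)
        if by_id[vid].chrom in ("X", "chrX"):
            col = col[female]
        if (col != MISSING).sum() == 0:
            continue
        if hwe_exact_test(*genotype_counts(col)) <= hwe_p_min:
            hwe_fail.append(vid)
    for vid in hwe_fail:
        report.variants_removed[vid] = "hwe"
    if hwe_fail:
        m = m.subset_variants([v for v in m.variant_ids if v not in set(hwe_fail)])

    kept_pruned = ld_prune(
        m, [by_id[v] for v in m.variant_ids], ld_window, ld_step, ld_r2_max
    )
    report.pruned_out = tuple(v for v in m.variant_ids if v not in set(kept_pruned))

    common = []
    for vid in kept_pruned:
        col = m.column(vid)
        if (col != MISSING).sum() == 0:
            continue
        if compute_maf(col) > common_maf:
            common.append(vid)
        else:
            report.variants_removed.setdefault(vid, "maf")
    report.kept_variants = tuple(common)
    report.m_effective = len(common)
    return m, report
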