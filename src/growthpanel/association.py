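"""Per-variant additive-dosage linear regression against phenotypes.

Each common variant (MAF strictly above 2%) is regressed, one at a time,
against each of the nine growth/IGF phenotype columns under an additive
genotype coding (0/1/2 alternate-allele dosage; hemizygous male X counts
as 2). Covariates default to sex, age, and the leading principal
components of the pruned dosage matrix. Two significance thresholds are
carried: a strict experiment-wide Bonferroni cut of alpha / m_effective
(m_effective = LD-pruned common variant count from QC) and a lenient
unadjusted cut of P <= 0.001 used by the cross-method overlap rule.

Missing data are handled by complete-case deletion per (variant,
phenotype) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .filtering import compute_maf
from .records import MISSING, GenotypeMatrix, PhenotypeTable, VariantRecord

LENIENT_P = 0.001
COMMON_MAF = 0.02


@dataclass
class MultipleTestingPlan:
    alpha: float
    m_effective: int
    lenient: float = LENIENT_P

    @property
    def strict(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_effective)


@dataclass
class AssociationResult:
    variant_id: str
    gene: str
    phenotype: str
    n: int
    beta: float
    se: float
    t: float
    p_raw: float
    passes_strict: bool
    passes_lenient: bool
    testable: bool = True


def bonferroni_threshold(alpha: float, m_effective: int) -> float:
    """Experiment-wide per-test threshold alpha / m_effective."""
    if m_effective < 1:
        raise ValueError("m_effective must be >= 1")
    return alpha / m_effective


def additive_dosage(cell: Union[int, float]) -> Union[int, float]:
    """Additive coding is the alt-allele count itself; missing propagates."""
    if cell == MISSING:
        return np.nan
    return cell


def linear_regression(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "",
    gene: str = "",
    phenotype: str = "",
    plan: Optional[MultipleTestingPlan] = None,
) -> AssociationResult:
    """OLS of phenotype on [intercept, dosage, covariates].

    Rows with any missing value are dropped; the reported P is the
    two-sided t-test on the dosage coefficient. A dosage that is constant
    after deletion yields an untestable result; collinear covariates raise.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosage, dtype=float)
    d = np.where(d == MISSING, np.nan, d)
    parts = [d[:, None]]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        parts.append(cov)
    X = np.column_stack(parts)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    yk, Xk = y[ok], X[ok]
    n = int(ok.sum())

    def _untestable() -> AssociationResult:
        return AssociationResult(
            variant_id, gene, phenotype, n, np.nan, np.nan, np.nan, np.nan,
            False, False, testable=False,
        )

    if n < Xk.shape[1] + 2 or np.nanstd(Xk[:, 0]) == 0:
        return _untestable()
    if Xk.shape[1] > 1:
        cov_rank = np.linalg.matrix_rank(Xk[:, 1:])
        if cov_rank < Xk.shape[1] - 1:
            raise ValueError(
                f"collinear covariates in regression for {variant_id}/{phenotype} "
                f"(rank {cov_rank} < {Xk.shape[1] - 1})"
            )
    model = sm.OLS(yk, sm.add_constant(Xk, has_constant="add"))
    fit = model.fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    strict = plan.strict if plan is not None else 0.0
    lenient = plan.lenient if plan is not None else LENIENT_P
    return AssociationResult(
        variant_id, gene, phenotype, n, beta, se, t, p,
        passes_strict=bool(p < strict),
        passes_lenient=bool(p <= lenient),
    )


def association_scan(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    variants: Sequence[VariantRecord],
    covariates: Optional[pd.DataFrame] = None,
    variant_subset: Optional[Sequence[str]] = None,
    m_effective: Optional[int] = None,
    alpha: float = 0.05,
    lenient: float = LENIENT_P,
) -> Tuple[List[AssociationResult], MultipleTestingPlan]:
    """Regress every common variant against every phenotype column.

    ``variant_subset`` (typically the QC report's analysis-ready set)
    restricts the scan; variants with cohort MAF <= 2% are excluded
    regardless. Samples without a phenotype row contribute nothing (the
    anonymized controls carry no phenotypes). ``covariates`` is indexed by
    sample id; rows missing from it are dropped.
    """
    by_id = {v.variant_id: v for v in variants}
    ids = list(variant_subset) if variant_subset is not None else list(matrix.variant_ids)
    scan_ids = []
    for vid in ids:
        col = matrix.column(vid)
        if (col != MISSING).sum() == 0:
            continue
        if compute_maf(col) > COMMON_MAF:
            scan_ids.append(vid)
    m_eff = m_effective if m_effective is not None else len(scan_ids)
    plan = MultipleTestingPlan(alpha=alpha, m_effective=max(m_eff, 1), lenient=lenient)

    pheno_samples = [s for s in phenotypes.sample_ids if s in set(matrix.sample_ids)]
    rows = [matrix.sample_index(s) for s in pheno_samples]
    cov_arr = None
    if covariates is not None and len(covariates.columns):
        cov_arr = covariates.reindex(pheno_samples).to_numpy(dtype=float)

    results: List[AssociationResult] = []
    dose_block = matrix.dosages[rows, :].astype(float)
    dose_block[dose_block == MISSING] = np.nan
    for name in phenotypes.phenotype_columns:
        y = phenotypes.frame[name].reindex(pheno_samples).to_numpy(dtype=float)
        if not np.isfinite(y).any():
            continue  # phenotype entirely missing: skip
        for vid in scan_ids:
            d = dose_block[:, matrix.variant_index(vid)]
            res = linear_regression(
                y, d, cov_arr,
                variant_id=vid,
                gene=by_id[vid].gene if vid in by_id else "",
                phenotype=name,
                plan=plan,
            )
            results.append(res)
    return results, plan


def association_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": r.variant_id,
            "gene": r.gene,
            "phenotype": r.phenotype,
            "n": r.n,
            "beta": r.beta,
            "se": r.se,
            "t": r.t,
            "p_raw": r.p_raw,
            "passes_strict": int(r.passes_strict),
            "passes_lenient": int(r.passes_lenient),
            "testable": int(r.testable),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gene", "phenotype", "n", "beta", "se", "t",
            "p_raw", "passes_strict", "passes_lenient", "testable",
        ],
    )
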