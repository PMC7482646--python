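"""Per-gene carriage-collapsing burden tests.

For each candidate gene, samples are collapsed to carrier (at least one
het or hom alternate genotype at any of the gene's variants in the chosen
subset) versus wild type, and the resulting case/control 2x2 table is
tested with Pearson's chi-squared (df = 1, no continuity correction by
default). The scan runs over three variant subsets — all variants, rare
variants only (MAF < 2%), and indels — with Bonferroni or
Benjamini-Hochberg correction across the genes tested. Both corrections
are exposed; by convention the all-variant scan is Bonferroni-corrected
and the rare-variant scan BH-corrected.

Samples missing at every subset variant of a gene are excluded from that
gene's table: carriage cannot be asserted from no data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .filtering import compute_maf
from .records import MISSING, GenotypeMatrix, PanelDefinition, VariantRecord

SUBSETS = ("all", "rare", "indel")
RARE_MAF = 0.02


@dataclass
class CarriageTable:
    gene: str
    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers

    @property
    def case_rate(self) -> float:
        return self.case_carriers / self.n_cases if self.n_cases else float("nan")

    @property
    def control_rate(self) -> float:
        return (
            self.control_carriers / self.n_controls if self.n_controls else float("nan")
        )


@dataclass
class BurdenResult:
    gene: str
    subset: str
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # increased / decreased / none
    significant: bool
    table: Optional[CarriageTable] = None


def _subset_mask(
    variants: Sequence[VariantRecord], matrix: GenotypeMatrix, subset: str
) -> np.ndarray:
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    mask = np.zeros(len(variants), dtype=bool)
    for i, v in enumerate(variants):
        if subset == "all":
            mask[i] = True
        elif subset == "indel":
            mask[i] = v.is_indel
        else:  # rare
            maf = v.annotation_maf
            if maf is None:
                col = matrix.column(v.variant_id)
                maf = compute_maf(col) if (col != MISSING).any() else 0.0
            mask[i] = maf < RARE_MAF
    return mask


def carriage_table(
    gene: str,
    variants: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    subset: str = "all",
) -> CarriageTable:
    """Collapse a gene's subset variants to carrier counts by group.

    A sample is a carrier iff it has at least one non-missing genotype >= 1
    at any subset variant of the gene; samples missing at all subset
    variants are excluded from both margins. A gene with no subset
    variants yields an all-noncarrier table over the full cohort.
    """
    gene_vars = [v for v in variants if v.gene == gene]
    mask = _subset_mask(gene_vars, matrix, subset)
    use = [v.variant_id for v, m in zip(gene_vars, mask) if m]
    case = matrix.case_mask
    if not use:
        return CarriageTable(
            gene, 0, int(case.sum()), 0, int((~case).sum())
        )
    cols = matrix.dosages[:, [matrix.variant_index(v) for v in use]]
    observed = (cols != MISSING).any(axis=1)
    carrier = (cols > 0).any(axis=1)
    cc = int((carrier & case & observed).sum())
    cn = int((~carrier & case & observed).sum())
    tc = int((carrier & ~case & observed).sum())
    tn = int((~carrier & ~case & observed).sum())
    return CarriageTable(gene, cc, cn, tc, tn)


def chi2_carriage_test(table: CarriageTable, yates: bool = False) -> Tuple[float, float, str]:
    """Pearson chi-squared (df=1) on the carrier/non-carrier 2x2 table.

    Returns (statistic, raw P, direction). Degenerate tables with a zero
    expected cell (no carriers anywhere, or everyone a carrier) give
    statistic 0, P = 1, direction ``none``. A zero case or control margin
    is an error.
    """
    obs = np.array(
        [
            [table.case_carriers, table.case_noncarriers],
            [table.control_carriers, table.control_noncarriers],
        ],
        dtype=float,
    )
    if obs[0].sum() == 0 or obs[1].sum() == 0:
        raise ValueError(f"{table.gene}: empty case or control margin")
    if (obs.sum(axis=0) == 0).any():
        return 0.0, 1.0, "none"
    stat, p, _, _ = chi2_contingency(obs, correction=yates)
    if table.case_rate > table.control_rate:
        direction = "increased"
    elif table.case_rate < table.control_rate:
        direction = "decreased"
    else:
        direction = "none"
    return float(stat), float(p), direction


def adjust_pvalues(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("P-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in ("benjamini_hochberg", "bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def burden_scan(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    panel: PanelDefinition,
    subset: str = "all",
    method: str = "bonferroni",
    alpha: float = 0.05,
    yates: bool = False,
) -> List[BurdenResult]:
    """One carriage burden test per panel gene, with multiplicity correction.

    ``m`` equals the number of panel genes; a result is significant when
    its adjusted P is at most ``alpha``. Results come back in panel order
    and can be sorted by adjusted P.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    by_gene: dict = {g: [] for g in panel.genes}
    for v in variants:
        if v.gene in by_gene:
            by_gene[v.gene].append(v)
    tables = []
    stats = []
    for gene in panel.genes:
        t = carriage_table(gene, by_gene[gene], matrix, subset)
        tables.append(t)
        if t.n_cases == 0 or t.n_controls == 0:
            stats.append((0.0, 1.0, "none"))
        else:
            stats.append(chi2_carriage_test(t, yates=yates))
    raw = [p for _, p, _ in stats]
    adj = adjust_pvalues(raw, method)
    out = []
    for gene, t, (stat, p, direction), pa in zip(panel.genes, tables, stats, adj):
        out.append(
            BurdenResult(
                gene=gene,
                subset=subset,
                statistic=stat,
                p_raw=p,
                p_adjusted=float(pa),
                direction=direction,
                significant=bool(pa <= alpha),
                table=t,
            )
        )
    return out


def burden_to_frame(results: Sequence[BurdenResult], panel: PanelDefinition) -> pd.DataFrame:
    """Tabular burden output with direction arrows and scientific-notation P."""
    rows = []
    for r in results:
        arrow = {"increased": "↑", "decreased": "↓", "none": ""}[r.direction]
        rows.append(
            {
                "gene": r.gene,
                "category": panel.category(r.gene) if r.gene in panel else "",
                "subset": r.subset,
                "direction": arrow,
                "chi2": round(r.statistic, 4),
                "p_raw": f"{r.p_raw:.3E}",
                "p_adjusted": f"{r.p_adjusted:.3E}",
                "significant": int(r.significant),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "category", "subset", "direction", "chi2",
            "p_raw", "p_adjusted", "significant",
        ],
    )
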