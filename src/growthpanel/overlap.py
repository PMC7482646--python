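"""Cross-method overlaps and diagnostic yield.

Overlap A is the set of genes significant in both carriage burden scans
(all variants, and rare variants only). Overlap B is the set of genes
picked up by the phenotype-association scan at the lenient threshold
(raw P <= 0.001 for at least one phenotype) that were also significant in
at least one burden scan. The triple overlap — burden-all, burden-rare
and association — is the headline gene set; diagnostic yield is the
fraction of the case cohort carrying at least one pathogenic or likely
pathogenic variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Set, Tuple


@dataclass
class OverlapReport:
    genes_all: FrozenSet[str]
    genes_rare: FrozenSet[str]
    genes_assoc: FrozenSet[str]
    yield_percent: Optional[float] = None

    @property
    def overlap_a(self) -> FrozenSet[str]:
        return self.genes_all & self.genes_rare

    @property
    def overlap_b(self) -> FrozenSet[str]:
        return (self.genes_all | self.genes_rare) & self.genes_assoc

    @property
    def triple(self) -> FrozenSet[str]:
        return self.overlap_a & self.genes_assoc


def overlap_a(genes_all: Iterable[str], genes_rare: Iterable[str]) -> FrozenSet[str]:
    """Genes significant in both burden scans (exact set intersection)."""
    return frozenset(genes_all) & frozenset(genes_rare)


def overlap_b(
    genes_all: Iterable[str],
    genes_rare: Iterable[str],
    genes_assoc: Iterable[str],
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """(overlap B, triple overlap) for the three gene sets."""
    a = frozenset(genes_all)
    r = frozenset(genes_rare)
    s = frozenset(genes_assoc)
    return (a | r) & s, (a & r) & s


def diagnostic_yield(
    calls: Iterable[Tuple[str, str]], n_cohort: int
) -> float:
    """Percent of the cohort with at least one P/LP finding.

    ``calls`` yields (patient_id, classification) pairs; distinct patients
    are counted, so multiple findings in one patient count once. Returns
    the exact percentage (callers round for display).
    """
    if n_cohort < 1:
        raise ValueError("n_cohort must be >= 1")
    hits: Set[str] = {
        pid
        for pid, cls in calls
        if cls in ("Pathogenic", "Likely pathogenic")
    }
    return 100.0 * len(hits) / n_cohort


def build_report(
    burden_all,
    burden_rare,
    association_results,
    yield_percent: Optional[float] = None,
) -> OverlapReport:
    """Assemble the overlap report from stage outputs.

    Burden inputs are :class:`~growthpanel.burden.BurdenResult` sequences;
    association genes use the lenient raw-P rule.
    """
    genes_all = frozenset(r.gene for r in burden_all if r.significant)
    genes_rare = frozenset(r.gene for r in burden_rare if r.significant)
    genes_assoc = frozenset(
        r.gene for r in association_results if r.testable and r.passes_lenient
    )
    return OverlapReport(genes_all, genes_rare, genes_assoc, yield_percent)
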