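"""Qualifying-variant selection: the diagnostic filter cascade.

A variant qualifies as potentially pathogenic when it is (a) carried by at
least one case and by no control, (b) exonic (missense, nonsense or
frameshift), (c) rare — MAF strictly below 2%, taking the annotation MAF
when present and the cohort MAF otherwise — and (d) its carriage fits the
gene's mode of inheritance. Missense variants must additionally be called
deleterious by at least 5 of the 10 in-silico prediction algorithms.

Known mutations are matched against a local lookup table on exact
gene + HGVS cDNA string; there is no fuzzy matching and no live database
access.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    EXONIC_CONSEQUENCES,
    INHERITANCE_MODES,
    MISSING,
    GenotypeMatrix,
    PanelDefinition,
    PredictionProfile,
    VariantRecord,
    zygosity_of,
)

#: Minimum number of deleterious calls for the vote to count as supporting.
VOTE_THRESHOLD = 5
#: Strict MAF cutoff for "rare".
RARE_MAF = 0.02


@dataclass(frozen=True)
class KnownMutation:
    gene: str
    hgvs_c: str
    classification: str
    source: str


@dataclass
class QualifyingVariant:
    """A variant that passed the diagnostic filter cascade."""

    record: VariantRecord
    carriers: Tuple[Tuple[str, str], ...]  # (sample_id, zygosity)
    cohort_maf: float
    case_only: bool
    inheritance_fit: bool
    deleterious_votes: int
    vote_supporting: bool
    known_match: Optional[KnownMutation] = None

    @property
    def carrier_ids(self) -> Tuple[str, ...]:
        return tuple(s for s, _ in self.carriers)


def compute_maf(column: np.ndarray) -> float:
    """Minor-allele frequency over the non-missing genotypes of one variant.

    Returns the lesser of the alt and ref allele frequencies, so a column
    fixed for the alternate allele has MAF 0.
    """
    col = np.asarray(column)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    alt_freq = float(obs.sum()) / (2.0 * obs.size)
    return min(alt_freq, 1.0 - alt_freq)


def deleterious_vote(profile: PredictionProfile) -> Tuple[int, bool]:
    """Count deleterious calls among the 10 algorithms.

    Missing calls count as non-deleterious (the vote counts positive
    calls); ``supporting`` is true at 5 or more deleterious calls.
    """
    votes = profile.n_deleterious
    return votes, votes >= VOTE_THRESHOLD


def inheritance_fit(
    zygosities: Sequence[str], mode: str, sexes: Optional[Sequence[str]] = None
) -> bool:
    """Does observed carriage fit the gene's mode of inheritance?

    AD: any het or hom carrier fits. AR: at least one homozygous carrier is
    required (compound heterozygotes are not accepted — no phasing). XL: a
    hemizygous male or homozygous female is required.
    """
    if mode not in INHERITANCE_MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    if len(zygosities) == 0:
        return False
    if sexes is None:
        sexes = ["male" if z == "hemi" else "female" for z in zygosities]
    if mode == "AD":
        return any(z in ("het", "hom") or z == "hemi" for z in zygosities)
    if mode == "AR":
        return any(z == "hom" for z in zygosities)
    return any(
        (z == "hemi" and s == "male") or (z == "hom" and s == "female")
        for z, s in zip(zygosities, sexes)
    )


def lookup_known_mutation(
    gene: str, hgvs_c: Optional[str], known_table: Optional[pd.DataFrame]
) -> Optional[KnownMutation]:
    """Exact gene + HGVS match against the known-mutation table."""
    if known_table is None or hgvs_c is None or len(known_table) == 0:
        return None
    hit = known_table[(known_table["gene"] == gene) & (known_table["hgvs_c"] == hgvs_c)]
    if hit.empty:
        return None
    row = hit.iloc[0]
    return KnownMutation(row["gene"], row["hgvs_c"], row["classification"], row["source"])


def select_qualifying_variants(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    panel: PanelDefinition,
    known_table: Optional[pd.DataFrame] = None,
    maf_max: float = RARE_MAF,
) -> List[QualifyingVariant]:
    """Apply the diagnostic filter cascade and return qualifying variants.

    The retained set is case-only, exonic, rare (strictly below
    ``maf_max``), inheritance-consistent, and — for missense — supported by
    the deleteriousness vote.
    """
    case_mask = genotypes.case_mask
    out: List[QualifyingVariant] = []
    for v in variants:
        if v.gene not in panel:
            raise ValueError(f"variant {v.variant_id}: gene {v.gene} absent from panel")
        col = genotypes.column(v.variant_id)
        carrier_rows = np.where(col > 0)[0]
        if carrier_rows.size == 0:
            continue
        control_carriers = int((~case_mask[carrier_rows]).sum())
        if control_carriers > 0:
            continue  # present in a control
        if v.consequence not in EXONIC_CONSEQUENCES:
            continue
        maf = v.annotation_maf if v.annotation_maf is not None else compute_maf(col)
        cohort_maf = compute_maf(col)
        if not (maf < maf_max):
            continue
        carriers = tuple(
            (
                genotypes.sample_ids[i],
                zygosity_of(int(col[i]), v.chrom, genotypes.sex[i]),
            )
            for i in carrier_rows
        )
        zygos = [z for _, z in carriers]
        sexes = [genotypes.sex[i] for i in carrier_rows]
        mode = panel.inheritance(v.gene)
        fit = inheritance_fit(zygos, mode, sexes)
        if not fit:
            continue
        votes, supporting = deleterious_vote(v.predictions)
        if v.consequence == "missense" and not supporting:
            continue
        out.append(
            QualifyingVariant(
                record=v,
                carriers=carriers,
                cohort_maf=cohort_maf,
                case_only=True,
                inheritance_fit=fit,
                deleterious_votes=votes,
                vote_supporting=supporting,
                known_match=lookup_known_mutation(v.gene, v.hgvs_c, known_table),
            )
        )
    return out


def qualifying_to_frame(qualifying: Sequence[QualifyingVariant]) -> pd.DataFrame:
    """Tabular view of the qualifying set (one row per variant)."""
    rows = []
    for q in qualifying:
        rows.append(
            {
                "variant_id": q.record.variant_id,
                "gene": q.record.gene,
                "consequence": q.record.consequence,
                "is_indel": q.record.is_indel,
                "cohort_maf": q.cohort_maf,
                "annotation_maf": q.record.annotation_maf,
                "n_carriers": len(q.carriers),
                "carriers": ";".join(f"{s}:{z}" for s, z in q.carriers),
                "deleterious_votes": q.deleterious_votes,
                "known_match": q.known_match.classification if q.known_match else "",
            }
        )
    cols = [
        "variant_id", "gene", "consequence", "is_indel", "cohort_maf",
        "annotation_maf", "n_carriers", "carriers", "deleterious_votes", "known_match",
    ]
    return pd.DataFrame(rows, columns=cols)
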