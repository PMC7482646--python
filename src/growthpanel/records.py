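"""Core data containers shared by every analysis stage.

The package operates on four in-memory objects: a list of
:class:`VariantRecord` (one per biallelic panel variant), a
:class:`GenotypeMatrix` (samples x variants alt-allele dosages with
case/control labels), a :class:`PhenotypeTable` (growth and IGF-axis
measurements, mostly as standard deviation scores), and a
:class:`PanelDefinition` (the candidate-gene panel with category,
inheritance mode and loss-of-function mechanism flags).

Genotypes are coded as alt-allele counts 0/1/2 with ``-1`` for a missing
call. Hemizygous male X genotypes are coded 0 or 2 (alt count doubled) so
that carriage and dosage logic stay uniform across chromosomes; zygosity
helpers recover hemizygosity from chromosome and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: The ten in-silico deleteriousness predictors whose calls are consumed by
#: the consensus vote, in canonical column order.
ALGORITHMS = (
    "polyphen2",
    "sift",
    "fathmm",
    "lrt",
    "mcap",
    "metalr",
    "metasvm",
    "mutation_assessor",
    "mutation_taster",
    "provean",
)

CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "synonymous", "other"})
#: Consequence classes treated as exonic/protein-altering by the filter cascade.
EXONIC_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift"})

PANEL_CATEGORIES = ("SS disease", "growth pathway", "adult height")
INHERITANCE_MODES = ("AD", "AR", "XL")

PHENOTYPE_COLUMNS = (
    "standing_height_sds",
    "sitting_height_sds",
    "birthweight_sds",
    "birth_length_sds",
    "target_height_sds",
    "head_circumference_sds",
    "igf1_sds",
    "igfbp3_sds",
    "als",
)


@dataclass(frozen=True)
class PredictionProfile:
    """Ternary deleteriousness calls for the ten prediction algorithms.

    Each slot is ``"D"`` (deleterious), ``"T"`` (tolerated) or ``None``
    (no call). Exactly one slot per algorithm in :data:`ALGORITHMS`.
    """

    calls: tuple = tuple([None] * 10)

    def __post_init__(self):
        if len(self.calls) != len(ALGORITHMS):
            raise ValueError(
                f"expected {len(ALGORITHMS)} prediction slots, got {len(self.calls)}"
            )
        for c in self.calls:
            if c not in ("D", "T", None):
                raise ValueError(f"invalid prediction call {c!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Optional[str]]) -> "PredictionProfile":
        unknown = set(mapping) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown prediction algorithms: {sorted(unknown)}")
        return cls(tuple(mapping.get(a) for a in ALGORITHMS))

    @classmethod
    def uniform(cls, call: Optional[str]) -> "PredictionProfile":
        return cls(tuple([call] * len(ALGORITHMS)))

    @property
    def n_deleterious(self) -> int:
        return sum(1 for c in self.calls if c == "D")

    @property
    def n_called(self) -> int:
        return sum(1 for c in self.calls if c is not None)

    def as_mapping(self) -> dict:
        return dict(zip(ALGORITHMS, self.calls))


@dataclass
class VariantRecord:
    """One biallelic panel variant with its annotations.

    ``consequence`` and ``annotation_maf`` arrive from upstream annotation
    (the package never annotates raw sequence); ``is_indel`` is derived
    from the allele lengths. Coordinates are 1-based inclusive, as in VCF.
    """

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    annotation_maf: Optional[float] = None
    predictions: PredictionProfile = field(default_factory=PredictionProfile)
    rs_id: Optional[str] = None
    hgvs_c: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.annotation_maf is not None and not (0.0 <= self.annotation_maf <= 1.0):
            raise ValueError(
                f"{self.variant_id}: annotation MAF {self.annotation_maf} outside [0, 1]"
            )

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with cohort labels.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids, variant_ids
        Unique identifiers for rows and columns.
    group
        Per-sample label, ``"case"`` or ``"control"``.
    sex
        Per-sample sex, ``"male"`` or ``"female"``.
    """

    def __init__(self, dosages, sample_ids, variant_ids, group, sex):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (samples x variants)")
        n, m = dosages.shape
        sample_ids = tuple(sample_ids)
        variant_ids = tuple(variant_ids)
        group = np.asarray(group, dtype=object)
        sex = np.asarray(sex, dtype=object)
        if len(sample_ids) != n or len(group) != n or len(sex) != n:
            raise ValueError("sample metadata length does not match dosage rows")
        if len(variant_ids) != m:
            raise ValueError("variant_ids length does not match dosage columns")
        if len(set(sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(variant_ids)) != m:
            raise ValueError("duplicate variant ids")
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage cells must be 0, 1, 2 or missing (-1)")
        if not set(group) <= {"case", "control"}:
            raise ValueError(f"unknown group labels: {set(group) - {'case', 'control'}}")
        if not set(sex) <= {"male", "female"}:
            raise ValueError(f"unknown sex labels: {set(sex) - {'male', 'female'}}")
        self.dosages = dosages
        self.sample_ids = sample_ids
        self.variant_ids = variant_ids
        self.group = group
        self.sex = sex
        self._vindex = {v: j for j, v in enumerate(variant_ids)}
        self._sindex = {s: i for i, s in enumerate(sample_ids)}

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.group == "case"

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    def variant_index(self, variant_id: str) -> int:
        return self._vindex[variant_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sindex[sample_id]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._vindex[variant_id]]

    def to_float(self) -> np.ndarray:
        """Dosages as float with missing cells mapped to NaN."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out

    # -- subsetting --------------------------------------------------------
    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(variant_ids)
        cols = [self._vindex[v] for v in ids]
        return GenotypeMatrix(
            self.dosages[:, cols], self.sample_ids, ids, self.group, self.sex
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(sample_ids)
        rows = [self._sindex[s] for s in ids]
        return GenotypeMatrix(
            self.dosages[rows, :], ids, self.variant_ids, self.group[rows], self.sex[rows]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.sample_ids, self.variant_ids,
            self.group.copy(), self.sex.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.group, other.group)
            and np.array_equal(self.sex, other.sex)
        )


def zygosity_of(dosage: int, chrom: str, sex: str) -> Optional[str]:
    """Classify a non-missing dosage as het / hom / hemi carrier state.

    Returns ``None`` for non-carriers (dosage 0). Male X genotypes, coded
    0 or 2, are reported as hemizygous.
    """
    if dosage in (MISSING, 0):
        return None
    if chrom in ("X", "chrX") and sex == "male":
        return "hemi"
    return "het" if dosage == 1 else "hom"


class PhenotypeTable:
    """Per-sample phenotype measurements, indexed by sample id.

    Recognised numeric columns are the nine analysis phenotypes in
    :data:`PHENOTYPE_COLUMNS` plus ``age_years``; ``sex`` is categorical.
    Unknown columns are preserved untouched. Any value may be missing.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" not in frame.columns:
                raise ValueError("phenotype table requires a sample_id column")
            frame = frame.set_index("sample_id")
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id values: {dups}")
        for col in (*PHENOTYPE_COLUMNS, "age_years"):
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                bad = vals.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
                if bad.any():
                    cell = frame.index[bad][0]
                    raise ValueError(
                        f"non-numeric value in column {col!r} for sample {cell!r}"
                    )
                if np.isinf(vals.dropna()).any():
                    raise ValueError(f"non-finite value in column {col!r}")
                frame[col] = vals
        self.frame = frame

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame.index)

    @property
    def phenotype_columns(self) -> tuple:
        return tuple(c for c in PHENOTYPE_COLUMNS if c in self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]


class PanelDefinition:
    """The candidate-gene panel: category, inheritance mode, LOF mechanism.

    Categories follow the panel's three selection groups (short-stature
    disease genes, growth-pathway genes, adult-height GWAS genes).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"gene", "category", "inheritance", "lof_mechanism"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if frame["gene"].duplicated().any():
            dups = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in panel: {dups}")
        bad_cat = set(frame["category"]) - set(PANEL_CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown panel categories: {sorted(bad_cat)}")
        bad_inh = set(frame["inheritance"]) - set(INHERITANCE_MODES)
        if bad_inh:
            raise ValueError(f"unknown inheritance modes: {sorted(bad_inh)}")
        frame["lof_mechanism"] = frame["lof_mechanism"].astype(int).astype(bool)
        self.frame = frame.set_index("gene", drop=False)

    @property
    def genes(self) -> tuple:
        return tuple(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def inheritance(self, gene: str) -> str:
        return self.frame.at[gene, "inheritance"]

    def category(self, gene: str) -> str:
        return self.frame.at[gene, "category"]

    def is_lof_mechanism(self, gene: str) -> bool:
        return bool(self.frame.at[gene, "lof_mechanism"])

    def subset(self, genes: Sequence[str]) -> "PanelDefinition":
        return PanelDefinition(self.frame.loc[list(genes)].reset_index(drop=True))
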