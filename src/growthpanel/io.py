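"""Readers and writers for the external file formats.

Genotypes travel as VCF 4.x (read through pysam, written as plain VCF
text); everything else — phenotypes, the gene panel, the sample sidecar,
known mutations, in-silico predictions, and the packaged printed-table
fixtures — is tab-delimited UTF-8 with a header row.

Case/control labels and sex live in a sidecar table (``sample_id``,
``group``, ``sex``) rather than in the VCF, because cases and controls
were sequenced as separate cohorts. Coordinates are 1-based inclusive.
Male X genotypes may be written haploid (``0`` / ``1``) and are read back
as dosages 0 / 2.
"""

from __future__ import annotations

import io as _stdio
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .records import (
    ALGORITHMS,
    MISSING,
    GenotypeMatrix,
    PanelDefinition,
    PhenotypeTable,
    PredictionProfile,
    VariantRecord,
)

FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "table3": "table3_phenotypes.tsv",
    "table4": "table4.tsv",
    "table5": "table5.tsv",
}


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sidecar, phenotypes, panel, predictions, known mutations
# ---------------------------------------------------------------------------

def read_sample_sidecar(path) -> pd.DataFrame:
    """Read the sample sidecar (sample_id, group, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sex"}
    if missing := required - set(df.columns):
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sidecar")
    return df


def write_sample_sidecar(path, matrix: GenotypeMatrix) -> None:
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": matrix.group, "sex": matrix.sex}
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a phenotype TSV; blanks become missing, extras are preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table requires a sample_id column")
    return PhenotypeTable(df)


def write_phenotype_table(path, table: PhenotypeTable) -> None:
    table.frame.to_csv(path, sep="\t", index=True)


def read_panel(path) -> PanelDefinition:
    return PanelDefinition(pd.read_csv(path, sep="\t"))


def write_panel(path, panel: PanelDefinition) -> None:
    out = panel.frame.reset_index(drop=True).copy()
    out["lof_mechanism"] = out["lof_mechanism"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> Dict[str, PredictionProfile]:
    """Read per-variant prediction calls (columns: variant_id + 10 algorithms).

    Cell values are ``D`` (deleterious), ``T`` (tolerated) or ``.`` / blank
    (no call).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    if missing := ({"variant_id", *ALGORITHMS} - set(df.columns)):
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        calls = tuple(None if row[a] in (".", "") else row[a] for a in ALGORITHMS)
        out[row["variant_id"]] = PredictionProfile(calls)
    return out


def write_predictions(path, variants: List[VariantRecord]) -> None:
    rows = []
    for v in variants:
        row = {"variant_id": v.variant_id}
        row.update({a: c or "." for a, c in v.predictions.as_mapping().items()})
        rows.append(row)
    pd.DataFrame(rows, columns=["variant_id", *ALGORITHMS]).to_csv(
        path, sep="\t", index=False
    )


def read_known_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := ({"gene", "hgvs_c", "classification", "source"} - set(df.columns)):
        raise ValueError(f"known-mutation table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_genotypes_vcf(path, matrix: GenotypeMatrix, variants: List[VariantRecord]) -> None:
    """Write the cohort as a plain-text VCF 4.2 file.

    Variant annotations (gene, consequence, annotation MAF, rs id, HGVS)
    ride in INFO; male X genotypes are written haploid.
    """
    vindex = {v.variant_id: v for v in variants}
    if set(vindex) != set(matrix.variant_ids):
        raise ValueError("variant records do not match matrix variant ids")
    order = sorted(
        matrix.variant_ids,
        key=lambda vid: (_chrom_sort_key(vindex[vid].chrom), vindex[vid].pos, vid),
    )
    chroms = []
    for vid in order:
        c = vindex[vid].chrom
        if c not in chroms:
            chroms.append(c)
    male_rows = np.asarray([s == "male" for s in matrix.sex])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=growthpanel\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##INFO=<ID=AMAF,Number=1,Type=Float,Description="Annotation MAF">\n')
        fh.write('##INFO=<ID=RS,Number=1,Type=String,Description="dbSNP id">\n')
        fh.write('##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS cDNA">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for vid in order:
            v = vindex[vid]
            col = matrix.column(vid)
            info = [f"GENE={v.gene}", f"CSQ={v.consequence}"]
            if v.annotation_maf is not None:
                info.append(f"AMAF={v.annotation_maf:.6g}")
            if v.rs_id:
                info.append(f"RS={v.rs_id}")
            if v.hgvs_c:
                info.append("HGVSC=" + v.hgvs_c.replace(" ", "_").replace(";", ","))
            haploid = (v.chrom in ("X", "chrX")) & male_rows
            gts = []
            for dose, hap in zip(col, haploid):
                if dose == MISSING:
                    gts.append("." if hap else "./.")
                elif hap:
                    gts.append("1" if dose == 2 else "0")
                else:
                    gts.append(("0/0", "0/1", "1/1")[dose])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotypes_vcf(vcf_path, sidecar_path) -> Tuple[GenotypeMatrix, List[VariantRecord]]:
    """Read a VCF plus sample sidecar into a GenotypeMatrix + variant records.

    Multi-allelic sites are split into one biallelic record per alternate
    allele (total alt dosage at the locus is conserved across the split);
    ``./.`` and half-calls become missing; haploid male X calls are doubled.
    """
    sidecar = read_sample_sidecar(sidecar_path).set_index("sample_id")
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path}: {exc}") from None
    samples = list(vf.header.samples)
    absent = [s for s in samples if s not in sidecar.index]
    if absent:
        raise ValueError(f"samples in VCF absent from sidecar: {absent}")
    group = sidecar.loc[samples, "group"].to_numpy()
    sex = sidecar.loc[samples, "sex"].to_numpy()

    variants: List[VariantRecord] = []
    columns: List[np.ndarray] = []
    lineno = len(str(vf.header).rstrip("\n").split("\n"))
    record_iter = iter(vf)
    while True:
        lineno += 1
        try:
            rec = next(record_iter)
        except StopIteration:
            break
        except Exception as exc:  # malformed record
            raise VcfParseError(f"malformed VCF record at line {lineno}: {exc}") from None
        alts = rec.alts or ()
        info = dict(rec.info)
        gene = info.get("GENE", "")
        csq = info.get("CSQ", "other")
        amaf = info.get("AMAF")
        rs = info.get("RS")
        hgvs = info.get("HGVSC")
        if hgvs:
            hgvs = hgvs.replace("_", " ")
        gts = [rec.samples[s].get("GT") for s in samples]
        for k, alt in enumerate(alts, start=1):
            dose = np.zeros(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                if gt is None or all(a is None for a in gt):
                    dose[i] = MISSING
                    continue
                if any(a is None for a in gt):  # half call
                    dose[i] = MISSING
                    continue
                count = sum(1 for a in gt if a == k)
                if len(gt) == 1:  # haploid call (male X)
                    count *= 2
                dose[i] = count
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            if len(alts) > 1:
                vid = f"{vid}_alt{k}"
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    gene=str(gene),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    consequence=str(csq),
                    annotation_maf=float(amaf) if amaf is not None else None,
                    rs_id=str(rs) if rs else None,
                    hgvs_c=hgvs,
                )
            )
            columns.append(dose)
    if columns:
        dosages = np.column_stack(columns)
    else:
        dosages = np.zeros((len(samples), 0), dtype=np.int8)
    matrix = GenotypeMatrix(
        dosages, samples, [v.variant_id for v in variants], group, sex
    )
    return matrix, variants


# ---------------------------------------------------------------------------
# packaged fixtures (the printed tables)
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("growthpanel.data").joinpath(name).read_text("utf-8")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged printed-table fixtures.

    ``table2`` carries the 27 classified diagnostic variants, ``table4`` /
    ``table5`` the all-variant and rare-variant burden hits with direction
    arrows and corrected P-values, ``table1`` the cohort baseline moments,
    and ``table3`` the per-patient phenotypes of the diagnosed cases.
    """
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_FILES)}")
    df = pd.read_csv(_stdio.StringIO(_data_text(FIXTURE_FILES[name])), sep="\t")
    return df


def default_panel() -> PanelDefinition:
    """The packaged 232-gene candidate panel."""
    return PanelDefinition(
        pd.read_csv(_stdio.StringIO(_data_text("panel.tsv")), sep="\t")
    )


def default_known_mutations() -> pd.DataFrame:
    """Packaged known-mutation table (a constructed local stand-in for
    Ensembl/LOVD lookups; see the file's provenance note in docs)."""
    return pd.read_csv(
        _stdio.StringIO(_data_text("known_mutations_synthetic.tsv")), sep="\t", dtype=str
    )
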