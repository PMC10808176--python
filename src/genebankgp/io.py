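"""Readers and writers for the pipeline's plain-text formats.

Phenotypes travel as long CSV (``accession_id,year,trait,value``),
genotypes as a TSV matrix (rows = accessions, columns = marker ids,
missing as NA) with optional VCF ingestion through cyvcf2, BLUEs as CSV
(``accession_id,trait,blue,se,n_years``), and kinship / distance matrices
as labeled TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import TraitBLUEs
from .genomics import GenotypeMatrix, KinshipMatrix

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_vcf",
    "write_vcf",
    "read_blues",
    "write_blues",
    "read_kinship",
    "write_kinship",
    "write_json",
]

PHENOTYPE_COLUMNS = ["accession_id", "year", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"accession_id": str, "year": str, "trait": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV lacks columns {sorted(missing)}")
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        accession_ids=[str(a) for a in df.index],
        marker_ids=[str(m) for m in df.columns],
        codes=df.to_numpy(dtype=float),
    )


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(matrix.codes, index=matrix.accession_ids, columns=matrix.marker_ids)
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic GT calls from a VCF as 0/1/2 alternative-allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (with gts012), 3 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    vcf.close()
    codes = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(accession_ids=samples, marker_ids=marker_ids, codes=codes)


def write_vcf(matrix: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Write a minimal single-chromosome VCF (GT only) for interchange."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accession_ids)
            + "\n"
        )
        for j, mid in enumerate(matrix.marker_ids):
            calls = [
                gt_map.get(c, "./.") if not np.isnan(c) else "./."
                for c in matrix.codes[:, j]
            ]
            fh.write(
                f"{chrom}\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_blues(path) -> dict[str, TraitBLUEs]:
    df = pd.read_csv(path, dtype={"accession_id": str, "trait": str})
    out = {}
    for trait, grp in df.groupby("trait"):
        grp = grp.set_index("accession_id")
        out[str(trait)] = TraitBLUEs(
            trait=str(trait),
            estimates=grp["blue"],
            standard_errors=grp["se"],
            n_years_mean=float(grp["n_years"].iloc[0]),
        )
    return out


def write_blues(blues: TraitBLUEs | list[TraitBLUEs], path) -> None:
    items = blues if isinstance(blues, list) else [blues]
    pd.concat([b.to_frame() for b in items]).to_csv(path, index=False)


def read_kinship(path, kind: str = "additive") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(
        labels=[str(a) for a in df.index], values=df.to_numpy(dtype=float), kind=kind
    )


def write_kinship(matrix: KinshipMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
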