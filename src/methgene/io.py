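"""Readers and writers for the standard interchange formats.

Genotypes go to/from VCFv4.2 (GT-only records, read back through cyvcf2)
or a plain TSV matrix; methylation and covariates are TSV; pedigrees are
FAM-style (FID IID PAT MAT SEX PHENO); gene definitions are BED (0-based
half-open on disk, 1-based inclusive in memory).  Scenario configs are
JSON or YAML with an explicit seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MISSING_GENOTYPE,
    GeneDefinition,
    GenotypeMatrix,
    MethylationMatrix,
    Pedigree,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_matrix_tsv",
    "read_methylation_tsv",
    "write_fam",
    "read_fam",
    "write_bed",
    "read_bed",
    "save_config",
    "load_config",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GENOTYPE: "./."}


def write_vcf(path: str | Path, geno: GenotypeMatrix, sample_ids: np.ndarray) -> None:
    """Plain-text VCFv4.2 with GT-only genotype fields (REF=A, ALT=C)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, sample_ids)) + "\n")
        for j in range(geno.n_snps):
            gts = "\t".join(_GT_CODE[int(g)] for g in geno.values[:, j])
            fh.write(
                f"{geno.chromosomes[j]}\t{geno.positions[j]}\t{geno.snp_ids[j]}"
                f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read genotypes (alt-allele counts) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    ids, pos, chrom, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        pos.append(var.POS)
        chrom.append(var.CHROM)
        g = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        g[g == 3] = MISSING_GENOTYPE
        rows.append(g)
    values = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return (
        GenotypeMatrix(
            values=values,
            snp_ids=np.array(ids),
            positions=np.array(pos),
            chromosomes=np.array(chrom),
        ),
        samples,
    )


def write_genotype_tsv(path: str | Path, geno: GenotypeMatrix, sample_ids: np.ndarray) -> None:
    df = pd.DataFrame(geno.values, index=sample_ids, columns=geno.snp_ids)
    df.replace(MISSING_GENOTYPE, pd.NA).to_csv(path, sep="\t", index_label="individual_id")


def read_genotype_tsv(
    path: str | Path, positions: np.ndarray, chromosomes: np.ndarray
) -> tuple[GenotypeMatrix, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    values = df.to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING_GENOTYPE, values).astype(np.int8)
    return (
        GenotypeMatrix(
            values=values,
            snp_ids=df.columns.to_numpy(),
            positions=np.asarray(positions),
            chromosomes=np.asarray(chromosomes),
        ),
        df.index.to_numpy(),
    )


def write_matrix_tsv(path: str | Path, values: np.ndarray, index, columns) -> None:
    pd.DataFrame(values, index=index, columns=columns).to_csv(
        path, sep="\t", index_label="individual_id"
    )


def read_methylation_tsv(
    path: str | Path, positions: np.ndarray, chromosomes: np.ndarray
) -> tuple[MethylationMatrix, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    return (
        MethylationMatrix(
            values=df.to_numpy(dtype=float),
            cpg_ids=df.columns.to_numpy(),
            positions=np.asarray(positions),
            chromosomes=np.asarray(chromosomes),
        ),
        df.index.to_numpy(),
    )


def write_fam(path: str | Path, ped: Pedigree, phenotype: np.ndarray | None = None) -> None:
    """FID IID PAT MAT SEX PHENO, whitespace-delimited."""
    df = ped.to_frame()
    df["pheno"] = -9 if phenotype is None else phenotype
    df.to_csv(path, sep=" ", header=False, index=False)


def read_fam(path: str | Path) -> Pedigree:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
        dtype=str,
    )
    idx = {iid: i for i, iid in enumerate(df["individual_id"])}
    father = np.array([idx.get(p, -1) for p in df["father_id"]], dtype=int)
    mother = np.array([idx.get(p, -1) for p in df["mother_id"]], dtype=int)
    return Pedigree(
        individual_id=df["individual_id"].to_numpy(),
        family_id=df["family_id"].to_numpy(),
        father=father,
        mother=mother,
        sex=df["sex"].astype(int).to_numpy(),
    )


def write_bed(path: str | Path, genes: list[GeneDefinition]) -> None:
    """BED (0-based half-open): chrom, start-1, stop, gene_id, category."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.stop}\t{g.gene_id}\t{g.category}\n")


def read_bed(path: str | Path) -> list[GeneDefinition]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, stop = parts[0], int(parts[1]), int(parts[2])
            gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{stop}"
            category = parts[4] if len(parts) > 4 else "noncausal"
            genes.append(GeneDefinition(gene_id, chrom, start0 + 1, stop, category))
    return genes


def save_config(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yml", ".yaml"}:
        return yaml.safe_load(text)
    return json.loads(text)
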