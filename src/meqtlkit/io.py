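"""Readers and writers for the plain-text interchange formats.

Genotypes: sample x SNP dosage TSV plus a SNP-map TSV (snp, chrom, pos,
ref, alt), or VCF with GT:DS fields. Phenotypes: feature x sample TSV plus
a feature-map TSV (feature, chrom, pos), positions 1-based. Kinship: square
TSV with a sample-id header (a headerless whitespace-delimited square
matrix is also accepted for interoperability with mixed-model tools).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CovariateTable, GenotypeSet, KinshipMatrix, PhenotypeMatrix

__all__ = [
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "read_phenotypes_tsv",
    "read_kinship_tsv",
    "read_covariates_tsv",
    "write_kinship_tsv",
    "write_assoc_tsv",
]


def read_genotypes_tsv(geno_path, snp_map_path) -> GenotypeSet:
    df = pd.read_csv(geno_path, sep="\t", index_col=0)
    snp_map = pd.read_csv(snp_map_path, sep="\t", index_col=0)
    name = snp_map.index.name
    snp_map = snp_map.loc[df.columns]
    snp_map.index.name = name
    return GenotypeSet(
        df.to_numpy(float), snp_map, [str(s) for s in df.index]
    )


def read_genotypes_vcf(path) -> GenotypeSet:
    """Parse a VCF with GT or GT:DS FORMAT fields into dosages."""
    samples, rows, snps = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, snp_id, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            cells = [c.split(":") for c in fields[9:]]
            if "DS" in fmt:
                k = fmt.index("DS")
                ds = [float(c[k]) for c in cells]
            else:
                k = fmt.index("GT")
                ds = [
                    sum(int(a) for a in c[k].replace("|", "/").split("/"))
                    for c in cells
                ]
            rows.append(ds)
            snps.append((snp_id, chrom, int(pos), ref, alt))
    snp_map = pd.DataFrame(
        snps, columns=["snp", "chrom", "pos", "ref", "alt"]
    ).set_index("snp")
    return GenotypeSet(np.array(rows, float).T, snp_map, list(samples))


def read_phenotypes_tsv(values_path, feature_map_path, scale="beta") -> PhenotypeMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    fmap = pd.read_csv(feature_map_path, sep="\t", index_col=0)
    return PhenotypeMatrix(
        df.to_numpy(float), fmap.loc[df.index], [str(s) for s in df.columns], scale
    )


def read_kinship_tsv(path, method: str = "centered-GRM") -> KinshipMatrix:
    first = open(path).readline()
    try:  # headerless GEMMA-style square matrix
        [float(x) for x in first.split()]
        K = np.loadtxt(path)
        ids = [f"s{i}" for i in range(K.shape[0])]
    except ValueError:
        df = pd.read_csv(path, sep="\t", index_col=0)
        K = df.to_numpy(float)
        ids = [str(s) for s in df.columns]
    return KinshipMatrix(K, ids, method)


def read_covariates_tsv(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", index_col=0))


def write_kinship_tsv(path, kin: KinshipMatrix) -> None:
    pd.DataFrame(kin.K, index=kin.sample_ids, columns=kin.sample_ids).to_csv(
        path, sep="\t"
    )


def write_assoc_tsv(path, records: pd.DataFrame) -> None:
    cols = ["chrom", "pos", "snp", "feature", "beta", "se", "p", "maf", "dist"]
    records.sort_values(["feature", "pos"])[cols].to_csv(
        path, sep="\t", index=False
    )
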