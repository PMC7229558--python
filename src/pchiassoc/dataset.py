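"""Case-control genotype container and file formats.

The in-memory unit of analysis is a :class:`GenotypeDataset`: an ``n x q``
matrix of minor-allele counts (0/1/2) with a binary phenotype.  Datasets are
read and written as plain dosage tables (TSV) and can be imported from VCF
via ``cyvcf2`` (GT fields, diallelic sites only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeDataset", "read_dosage", "write_dosage", "read_vcf"]


@dataclass
class GenotypeDataset:
    """Minor-allele-count genotypes with a binary case-control phenotype.

    Rows are samples, columns are SNPs; entries are 0, 1 or 2 minor alleles.
    Both phenotype classes must be non-empty.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, q = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length must match the number of samples")
        if len(self.snp_ids) != q:
            raise ValueError("one SNP id per genotype column is required")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be minor-allele counts in {0, 1, 2}")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")
        if self.phenotype.min() == self.phenotype.max():
            raise ValueError("both phenotype classes (cases and controls) must be present")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def q(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def column_index(self, snp: int | str) -> int:
        """Resolve a SNP given as 0-based index or as an id string."""
        if isinstance(snp, str):
            try:
                return self.snp_ids.index(snp)
            except ValueError:
                raise KeyError(f"unknown SNP id {snp!r}") from None
        k = int(snp)
        if not 0 <= k < self.q:
            raise IndexError(f"SNP index {k} outside 0..{self.q - 1}")
        return k

    def subset(self, snps: Sequence[int | str]) -> "GenotypeDataset":
        """A dataset restricted to the given SNP columns (order preserved)."""
        idx = [self.column_index(s) for s in snps]
        return GenotypeDataset(
            self.genotypes[:, idx], self.phenotype, [self.snp_ids[i] for i in idx]
        )

    def drop(self, snps: Sequence[int | str]) -> "GenotypeDataset":
        """A dataset with the given SNP columns removed."""
        out = set(self.column_index(s) for s in snps)
        keep = [k for k in range(self.q) if k not in out]
        return self.subset(keep)


def write_dosage(data: GenotypeDataset, path: str | Path) -> None:
    """Write a TSV dosage table: header ``phenotype <ids...>``, int rows."""
    df = pd.DataFrame(data.genotypes, columns=data.snp_ids)
    df.insert(0, "phenotype", data.phenotype)
    df.to_csv(path, sep="\t", index=False)


def _resolve_missing(
    genotypes: np.ndarray, phenotype: np.ndarray, missing: str
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the missing-genotype policy: drop samples or impute per SNP.

    Imputation replaces a missing entry by the rounded per-SNP mean count so
    that the 0/1/2 coding is preserved.
    """
    miss = np.isnan(genotypes)
    if not miss.any():
        return genotypes.astype(np.int8), phenotype
    if missing == "drop":
        keep = ~miss.any(axis=1)
        return genotypes[keep].astype(np.int8), phenotype[keep]
    if missing == "mean":
        col_mean = np.nanmean(genotypes, axis=0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        idx = np.where(miss)
        genotypes = genotypes.copy()
        genotypes[idx] = fill[idx[1]]
        return genotypes.astype(np.int8), phenotype
    raise ValueError(f"unknown missing policy {missing!r} (use 'drop' or 'mean')")


def read_dosage(path: str | Path, missing: str = "drop") -> GenotypeDataset:
    """Read a TSV dosage table written by :func:`write_dosage`.

    Empty cells and ``NA`` are treated as missing and resolved by the
    ``missing`` policy ('drop' samples, default, or 'mean' impute).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", "na", "."])
    if df.columns[0] != "phenotype":
        raise ValueError("dosage table must start with a 'phenotype' column")
    phenotype = df["phenotype"].to_numpy(dtype=np.int8)
    genotypes = df.drop(columns="phenotype").to_numpy(dtype=float)
    genotypes, phenotype = _resolve_missing(genotypes, phenotype, missing)
    return GenotypeDataset(genotypes, phenotype, list(df.columns[1:]))


def read_vcf(
    path: str | Path,
    phenotype: Mapping[str, int] | Sequence[int],
    missing: str = "drop",
) -> GenotypeDataset:
    """Read GT fields from a VCF into a minor-allele-count dataset.

    ``phenotype`` is either a mapping sample-name -> 0/1 or a sequence
    aligned with the VCF sample order.  Multi-allelic sites are rejected.
    The ALT-allele dosage is flipped at sites where ALT is the major allele
    in the pooled sample, so columns always count the minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if isinstance(phenotype, Mapping):
        pheno = np.array([phenotype[s] for s in samples], dtype=np.int8)
    else:
        pheno = np.asarray(phenotype, dtype=np.int8)
        if pheno.shape != (len(samples),):
            raise ValueError("phenotype length must match the VCF sample count")
    cols, ids = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} is not supported"
            )
        g = variant.gt_types.astype(float)  # 0/1/2 ALT copies, 3 = missing
        g[g == 3] = np.nan
        cols.append(g)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    if not cols:
        raise ValueError("VCF contains no variants")
    genotypes = np.column_stack(cols)
    # flip to minor-allele counts where ALT is the major allele
    alt_freq = np.nanmean(genotypes, axis=0) / 2.0
    flip = alt_freq > 0.5
    genotypes[:, flip] = 2.0 - genotypes[:, flip]
    genotypes, pheno = _resolve_missing(genotypes, pheno, missing)
    return GenotypeDataset(genotypes, pheno, ids)
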