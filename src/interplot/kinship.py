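"""Additive genomic relationship matrices from SNP dosages.

Dosages are counts of the alternate allele in [0, 2] per genotype and
marker.  Markers are screened on minor allele frequency and the
relationship matrix uses the centred cross-product (VanRaden method 1):

    K = W W' / (2 * sum_m p_m (1 - p_m)),   W = dosages - 2 p

with p_m the alternate-allele frequency of marker m.  Missing dosages
are mean-imputed per marker before centring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DosageMatrix", "KinshipMatrix", "filter_maf", "additive_grm"]

#: ridge added to the diagonal wherever K must be Cholesky-factored
KINSHIP_RIDGE = 1e-6


@dataclass(frozen=True)
class DosageMatrix:
    """Genotypes x markers allele dosages with IDs; NaN marks missing."""

    dosages: np.ndarray
    genotype_ids: list
    marker_ids: list

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (genotypes x markers)")
        if d.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match ID lists")
        with np.errstate(invalid="ignore"):
            if np.nanmin(d, initial=0) < 0 or np.nanmax(d, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if np.isnan(d).all(axis=1).any():
            raise ValueError("genotype with all-missing dosages")

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    @classmethod
    def from_csv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)), list(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.dosages, index=self.genotype_ids, columns=self.marker_ids).to_csv(
            path, index_label="genotype"
        )

    @classmethod
    def from_vcf(cls, path) -> "DosageMatrix":
        """Read GT fields from a VCF into alternate-allele dosages."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        rows, markers = [], []
        for var in vcf:
            gts = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
            dose = np.where(gts == 3, np.nan, np.where(gts == 2, 2.0, gts)).astype(float)
            rows.append(dose)
            markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        return cls(np.asarray(rows).T, ids, markers)


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric g x g genomic relationship matrix with genotype IDs."""

    values: np.ndarray
    genotype_ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.genotype_ids), len(self.genotype_ids)):
            raise ValueError("K shape does not match ID list")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("K must be symmetric")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    def subset(self, ids) -> "KinshipMatrix":
        pos = {gid: i for i, gid in enumerate(self.genotype_ids)}
        idx = np.array([pos[g] for g in ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids))

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise ValueError("kinship CSV must be square with matching labels")
        return cls(df.to_numpy(float), list(df.index.astype(str)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids).to_csv(
            path, index_label="genotype"
        )


def filter_maf(d: DosageMatrix, threshold: float = 0.01) -> DosageMatrix:
    """Keep markers whose minor allele frequency is strictly above ``threshold``."""
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = d.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    if not keep.any():
        raise ValueError(
            f"no marker passes MAF > {threshold}: check dosage coding or threshold"
        )
    return DosageMatrix(
        d.dosages[:, keep],
        d.genotype_ids,
        [m for m, k in zip(d.marker_ids, keep) if k],
    )


def additive_grm(d: DosageMatrix) -> KinshipMatrix:
    """Centred cross-product relationship matrix (VanRaden method 1)."""
    if d.n_genotypes < 2:
        raise ValueError("need at least two genotypes")
    if d.n_markers < 1:
        raise ValueError("need at least one marker")
    X = d.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: relationship matrix undefined")
    W = X - 2.0 * p
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(d.genotype_ids))
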