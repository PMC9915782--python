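"""Linkage-disequilibrium estimation from a reference genotype panel.

The GLS estimators need the signed Pearson correlation r between
instrument dosages (not r-squared: the sign of the correlation enters the
covariance of the summary estimates). This module loads a reference panel
from a VCF or a plain dosage table, computes the signed LD matrix, and
conditions it to positive definiteness so it can be inverted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class GenotypePanel:
    """Reference genotypes as a sample x variant dosage matrix in [0, 2].

    Missing dosages are mean-imputed per variant at load time, which keeps
    any correlation matrix computed from the panel positive semi-definite
    by construction.
    """

    variant_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants), float
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sample x variant matrix")
        if self.dosages.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids length does not match dosage columns")

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[0]

    def monomorphic_ids(self) -> list[str]:
        """Variants with zero dosage variance (unusable for LD)."""
        var = self.dosages.var(axis=0)
        return [vid for vid, v in zip(self.variant_ids, var) if v == 0.0]

    def frequencies(self) -> dict[str, float]:
        """Effect-allele (ALT/dosage) frequency per variant."""
        freq = self.dosages.mean(axis=0) / 2.0
        return dict(zip(self.variant_ids, freq))


@dataclass
class LDMatrix:
    """Signed Pearson correlation matrix over an ordered variant set."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("r must be square and match variant_ids")

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"variants not in LD matrix: {missing}")
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = self.indices(ids)
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def flip(self, signs: np.ndarray) -> "LDMatrix":
        """Apply per-variant sign flips: R -> S R S with S = diag(signs)."""
        s = np.asarray(signs, dtype=float)
        return LDMatrix(list(self.variant_ids), self.r * np.outer(s, s))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.r, columns=self.variant_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(list(df.columns), df.to_numpy(dtype=float))


def _load_vcf(path: Path, variant_subset: Sequence[str] | None):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    wanted = None if variant_subset is None else set(variant_subset)
    ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if wanted is not None and vid not in wanted:
            continue
        gt = np.array(var.genotypes, dtype=float)[:, :2]
        gt[gt < 0] = np.nan  # missing alleles
        cols.append(gt.sum(axis=1))
        ids.append(vid)
    samples = list(vcf.samples)
    vcf.close()
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return ids, dos, samples


def _load_dosage_table(path: Path, variant_subset: Sequence[str] | None):
    df = pd.read_csv(path, sep=r"\s+", compression="infer")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    df = df.iloc[:, 1:]
    ids = list(df.columns)
    if variant_subset is not None:
        keep = [v for v in ids if v in set(variant_subset)]
        df = df[keep]
        ids = keep
    return ids, df.to_numpy(dtype=float), sample_ids


def load_panel(
    path: str | Path,
    variant_subset: Sequence[str] | None = None,
) -> GenotypePanel:
    """Load a reference panel from a VCF or a plain dosage table.

    VCF genotypes are converted to ALT-allele counts; a dosage table is
    whitespace-delimited with sample ids in the first column and one
    variant per remaining column. Only ``variant_subset`` variants are
    kept when given (panel reordered to match it); a requested variant
    absent from the file is a hard error. Missing dosages are
    mean-imputed per variant.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if ".vcf" in suffixes or suffixes.endswith(".bcf"):
        ids, dos, samples = _load_vcf(path, variant_subset)
    else:
        ids, dos, samples = _load_dosage_table(path, variant_subset)

    if variant_subset is not None:
        lookup = {v: i for i, v in enumerate(ids)}
        missing = [v for v in variant_subset if v not in lookup]
        if missing:
            raise KeyError(f"{path}: requested variants not found: {missing}")
        order = [lookup[v] for v in variant_subset]
        ids = list(variant_subset)
        dos = dos[:, order]

    # per-variant mean imputation of missing dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]

    out_of_range = (dos < 0) | (dos > 2)
    if out_of_range.any():
        raise ValueError(f"{path}: dosages outside [0, 2]")
    return GenotypePanel(variant_ids=ids, dosages=dos, sample_ids=samples)


def compute_ld(
    panel: GenotypePanel,
    ids: Sequence[str] | None = None,
    condition: bool = True,
    epsilon: float = 1e-4,
) -> LDMatrix:
    """Signed pairwise Pearson correlation of panel dosage columns.

    Monomorphic variants are a hard error (their correlation is
    undefined). By default the result is conditioned to positive
    definiteness with :func:`condition_pd`; pass ``condition=False`` for
    the raw sample correlations.
    """
    if ids is None:
        ids = list(panel.variant_ids)
    lookup = {v: i for i, v in enumerate(panel.variant_ids)}
    missing = [v for v in ids if v not in lookup]
    if missing:
        raise KeyError(f"variants not in panel: {missing}")
    idx = [lookup[v] for v in ids]
    X = panel.dosages[:, idx]
    var = X.var(axis=0)
    mono = [v for v, s in zip(ids, var) if s == 0.0]
    if mono:
        raise ValueError(f"monomorphic variants in LD computation: {mono}")

    if len(ids) == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    ld = LDMatrix(list(ids), r)
    return condition_pd(ld, epsilon) if condition else ld


def condition_pd(ld: LDMatrix, epsilon: float = 1e-4) -> LDMatrix:
    """Floor eigenvalues at ``epsilon * lambda_max`` and restore unit diagonal.

    The diagonal is restored by the symmetric scaling D^-1/2 A D^-1/2,
    which preserves positive definiteness; an already well-conditioned
    matrix passes through unchanged up to floating-point error.
    """
    a = (ld.r + ld.r.T) / 2.0
    w, v = np.linalg.eigh(a)
    floor = epsilon * w[-1]
    if w[-1] <= 0:
        raise ValueError("LD matrix has no positive eigenvalue")
    w = np.maximum(w, floor)
    a = (v * w) @ v.T
    a = (a + a.T) / 2.0
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    np.fill_diagonal(a, 1.0)
    return LDMatrix(list(ld.variant_ids), a)
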