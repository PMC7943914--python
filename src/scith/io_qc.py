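"""Quality control, library-size log-normalization, and the HVG/PCA embedding.

QC removes cells that express fewer than ``min_genes`` genes, more than ``max_genes``
genes, or carry more than ``max_mito_fraction`` of their counts in mitochondrial
(``MT-``-prefixed) genes; all three removals are strict inequalities, so boundary
cells are retained. Normalization is the LogNormalize convention,
``x -> ln(1 + 1e4 * x / library_size)``. The embedding selects the top highly
variable genes by 20-bin standardized dispersion, centers and scales them, and runs
an exact-SVD PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from sklearn.decomposition import PCA

from .simulate import MITO_PREFIX

log = logging.getLogger(__name__)

__all__ = ["QcThresholds", "Embedding", "apply_qc", "normalize_log", "select_hvg_and_pca"]


@dataclass(frozen=True)
class QcThresholds:
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.20

    def __post_init__(self):
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class Embedding:
    """Per-cell PCA coordinates with the variance each component explains."""

    coordinates: np.ndarray  # cells x D
    explained_variance: np.ndarray  # length D, nonincreasing
    explained_variance_ratio: np.ndarray
    hvg: list  # gene names used as features
    barcodes: list

    def top(self, d: int) -> np.ndarray:
        return self.coordinates[:, : min(d, self.coordinates.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.barcodes, columns=cols)


def _counts_per_cell(X) -> tuple[np.ndarray, np.ndarray]:
    """(detected genes per cell, total counts per cell)."""
    if sparse.issparse(X):
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        detected = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
    return detected, total


def apply_qc(adata: ad.AnnData, thresholds: QcThresholds = QcThresholds()):
    """Filter cells by detected-gene count and mitochondrial fraction.

    Returns ``(filtered_adata, report)``. The report counts removals per criterion
    with a fixed precedence (too few genes, then too many genes, then high mito), so
    the per-criterion counts partition the total removed.
    """
    detected, total = _counts_per_cell(adata.X)
    mito_mask = adata.var_names.str.startswith(MITO_PREFIX)
    if sparse.issparse(adata.X):
        mito_counts = np.asarray(adata.X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = adata.X[:, mito_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    low = detected < thresholds.min_genes
    high = ~low & (detected > thresholds.max_genes)
    mito = ~low & ~high & (mito_frac > thresholds.max_mito_fraction)
    keep = ~(low | high | mito)

    report = {
        "n_input": int(adata.n_obs),
        "n_removed_low_genes": int(low.sum()),
        "n_removed_high_genes": int(high.sum()),
        "n_removed_high_mito": int(mito.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "thresholds": {
            "min_genes": thresholds.min_genes,
            "max_genes": thresholds.max_genes,
            "max_mito_fraction": thresholds.max_mito_fraction,
        },
    }
    if report["n_kept"] == 0:
        warnings.warn("all cells removed by QC; downstream stages will be empty",
                      stacklevel=2)
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    out.obs["total_counts"] = total[keep]
    out.obs["mito_fraction"] = mito_frac[keep]
    return out, report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """LogNormalize in place: keep raw counts in ``layers['counts']`` and replace
    ``X`` with ``ln(1 + target_sum * x / library_size)``.

    Zero counts stay exactly zero; a zero-library cell (impossible after QC) is an
    error rather than a silent NaN.
    """
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    lib = np.asarray(X.sum(axis=1)).ravel()
    if adata.n_obs and lib.min() <= 0:
        raise ValueError("cell with zero library size; run QC first")
    adata.layers["counts"] = X.copy()
    Xn = X.astype(np.float64).tocsr(copy=True)
    scale = target_sum / np.maximum(lib, 1e-300)
    Xn = sparse.diags(scale) @ Xn
    Xn.data = np.log1p(Xn.data)
    adata.X = Xn.tocsr()
    adata.uns["normalization"] = {"method": "LogNormalize", "target_sum": target_sum}
    return adata


def select_hvg_and_pca(
    adata: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 50,
) -> Embedding:
    """Pick the top ``n_hvg`` genes by binned standardized dispersion, scale, and PCA.

    Mirrors the Seurat-style workflow: dispersion of expm1'd log data standardized
    within 20 mean bins, feature centering/scaling, then exact-SVD PCA with a
    deterministic sign convention. Also records ``adata.obsm['X_pca']`` and
    ``adata.var['highly_variable']``.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells for an embedding")
    X = adata.X
    mean, var = _gene_moments(X)
    if var.max() <= 0:
        raise ValueError("no variable genes: expression matrix is constant")

    if n_hvg < adata.n_vars:
        sub = adata.copy()
        sc.pp.highly_variable_genes(sub, flavor="seurat", n_top_genes=n_hvg)
        hvg_mask = sub.var["highly_variable"].to_numpy()
        # guard: never include zero-variance genes as features
        hvg_mask &= var > 0
    else:
        hvg_mask = var > 0
    hvg = adata.var_names[hvg_mask].tolist()
    adata.var["highly_variable"] = hvg_mask

    M = X[:, hvg_mask]
    M = M.toarray() if sparse.issparse(M) else np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd

    d = int(min(n_pcs, Z.shape[1], max(1, adata.n_obs - 1)))
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(Z)
    # deterministic sign: largest-magnitude loading of each component is positive
    for j in range(d):
        k = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, k] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1

    emb = Embedding(
        coordinates=coords,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        hvg=hvg,
        barcodes=adata.obs_names.tolist(),
    )
    adata.obsm["X_pca"] = coords
    adata.uns["pca"] = {"explained_variance": emb.explained_variance,
                        "explained_variance_ratio": emb.explained_variance_ratio}
    return emb


def _gene_moments(X) -> tuple[np.ndarray, np.ndarray]:
    if sparse.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = (np.asarray(X) ** 2).mean(axis=0)
    return mean, np.maximum(sq - mean**2, 0.0)
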