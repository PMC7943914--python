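"""Expression-inferred copy-number profiles and per-cell malignancy scoring.

The inference follows the inferCNV recipe: per-gene log-ratio of each cell against
the mean of a diploid reference population (immune/stromal cells), clipped to a
fixed magnitude, smoothed by a moving average over genome-ordered genes within each
chromosome (the window shrinks at chromosome edges), and recentred by each cell's
median. The malignancy score of a cell is the mean squared entry of its smoothed
profile; cells are flagged putatively malignant when the score exceeds the 95th
percentile of the reference scores *and* the profile correlates (> 0.3) with the
mean profile of the top-5%-scoring cells. The two-criterion flag protects against
high-variance but diploid cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["CnvProfile", "MalignancyScore", "infer_cnv", "malignancy_score"]

LOG2 = np.log(2.0)


@dataclass
class CnvProfile:
    """Smoothed per-cell log2-ratio matrix over genome-ordered genes."""

    matrix: np.ndarray  # cells x ordered genes
    genes: list  # gene names in genome order
    gene_order: pd.DataFrame  # chrom / ordinal per kept gene
    barcodes: list
    reference_cells: list
    window: int
    clip: float
    dropped_genes: list


@dataclass
class MalignancyScore:
    """Per-cell mean-squared-CNV score with reference summary and flags."""

    scores: pd.Series  # indexed by barcode
    flags: pd.Series  # boolean, putatively malignant
    reference_mean: float
    reference_sd: float
    reference_q95: float
    score_quantile: float
    corr_min: float


def _moving_average_blocks(M: np.ndarray, chrom: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 1 within each chromosome block, window shrinking at
    the edges so every position averages over the genes actually available."""
    half = window // 2
    out = np.empty_like(M)
    for c in pd.unique(chrom):
        cols = np.nonzero(chrom == c)[0]
        B = M[:, cols]
        g = B.shape[1]
        if g < max(1, window // 4):
            warnings.warn(
                f"chromosome {c!r} has only {g} mapped genes for window {window}",
                stacklevel=3)
        cs = np.cumsum(B, axis=1)
        cs = np.concatenate([np.zeros((B.shape[0], 1)), cs], axis=1)
        pos = np.arange(g)
        lo = np.maximum(pos - half, 0)
        hi = np.minimum(pos + half, g - 1)
        out[:, cols] = (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)
    return out


def infer_cnv(
    adata,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
    min_reference: int = 30,
    min_mean: float = 0.1,
) -> CnvProfile:
    """Infer smoothed per-cell CNV profiles from a log-normalized matrix.

    ``adata.var`` must carry ``chrom`` and ``ordinal`` columns (genome order);
    genes without a position, and near-silent genes (mean normalized expression
    below ``min_mean``, the usual inferCNV expression cutoff), are dropped and
    logged. ``reference_cells`` is a collection of barcodes assumed diploid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    ref = pd.Index(reference_cells)
    ref = ref[ref.isin(adata.obs_names)]
    if len(ref) < min_reference:
        raise ValueError(
            f"need at least {min_reference} reference cells, got {len(ref)}")

    var = adata.var
    mapped = var["chrom"].notna() & var["ordinal"].notna()
    Xfull = adata.X
    gene_mean = (np.asarray(Xfull.mean(axis=0)).ravel() if sparse.issparse(Xfull)
                 else np.asarray(Xfull, dtype=float).mean(axis=0))
    mapped &= gene_mean >= min_mean
    dropped = adata.var_names[~mapped].tolist()
    if dropped:
        log.info("dropping %d genes (no position or mean expression < %g)",
                 len(dropped), min_mean)
    if not mapped.any():
        raise ValueError("no genes usable for CNV inference")
    order = np.argsort(var.loc[mapped, "ordinal"].to_numpy(), kind="stable")
    genes = adata.var_names[mapped][order].tolist()

    X = adata[:, genes].X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    ref_idx = adata.obs_names.isin(ref)
    ref_mean = X[ref_idx].mean(axis=0)

    # log2-ratio against the reference, clipped before smoothing
    R = (X - ref_mean) / LOG2
    np.clip(R, -clip, clip, out=R)
    chrom = var.loc[genes, "chrom"].to_numpy()
    S = _moving_average_blocks(R, chrom, window)
    S -= np.median(S, axis=1, keepdims=True)

    return CnvProfile(
        matrix=S,
        genes=genes,
        gene_order=var.loc[genes, ["chrom", "ordinal"]].copy(),
        barcodes=adata.obs_names.tolist(),
        reference_cells=ref.tolist(),
        window=window,
        clip=clip,
        dropped_genes=dropped,
    )


def malignancy_score(
    profile: CnvProfile,
    score_quantile: float = 0.95,
    corr_min: float = 0.3,
    top_fraction: float = 0.05,
) -> MalignancyScore:
    """Score cells by mean squared CNV and flag putatively malignant ones.

    A cell is flagged when its score exceeds the ``score_quantile`` quantile of the
    reference cells' scores and its profile correlates above ``corr_min`` with the
    mean profile of the top ``top_fraction`` highest-scoring cells.
    """
    S = profile.matrix
    scores = (S**2).mean(axis=1) if S.size else np.zeros(len(profile.barcodes))
    scores_s = pd.Series(scores, index=profile.barcodes, name="malignancy_score")

    ref_mask = pd.Index(profile.barcodes).isin(profile.reference_cells)
    ref_scores = scores[ref_mask]
    ref_mean = float(ref_scores.mean()) if ref_scores.size else 0.0
    ref_sd = float(ref_scores.std(ddof=1)) if ref_scores.size > 1 else 0.0
    ref_q95 = float(np.quantile(ref_scores, score_quantile)) if ref_scores.size else 0.0

    flags = np.zeros(len(scores), dtype=bool)
    if scores.max() > 0:
        n_top = max(1, int(np.ceil(top_fraction * len(scores))))
        top_idx = np.argsort(scores)[::-1][:n_top]
        anchor = S[top_idx].mean(axis=0)
        a = anchor - anchor.mean()
        denom_a = np.sqrt((a**2).sum())
        if denom_a > 0:
            C = S - S.mean(axis=1, keepdims=True)
            denom_c = np.sqrt((C**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(denom_c > 0, C @ a / (denom_c * denom_a), 0.0)
            flags = (scores > ref_q95) & (corr > corr_min)

    return MalignancyScore(
        scores=scores_s,
        flags=pd.Series(flags, index=profile.barcodes, name="putatively_malignant"),
        reference_mean=ref_mean,
        reference_sd=ref_sd,
        reference_q95=ref_q95,
        score_quantile=score_quantile,
        corr_min=corr_min,
    )
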