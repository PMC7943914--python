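"""Wilcoxon rank-sum differential expression, condition-related gene sets, and the
domain-cluster composition rule.

``rank_sum_test`` is the shared two-sided rank-sum primitive: exact by enumeration of
all group assignments (midranks handle ties) when the combined sample is small, and
the tie-corrected normal approximation otherwise. ``wilcoxon_de`` vectorizes the
same test across genes, pairs it with an expm1-mean log2 fold change, and adjusts
p-values by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["rank_sum_test", "wilcoxon_de", "condition_genes", "domain_clusters"]

EXACT_MAX_N = 12  # exact enumeration up to C(12, 6) = 924 assignments
LFC_PSEUDOCOUNT = 1e-9


def _tie_sum(values: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def _asymptotic_p(W: float, nA: int, nB: int, tie_sum: float) -> float:
    n = nA + nB
    mu = nA * (n + 1) / 2.0
    var = nA * nB / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (W - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _exact_p(values: np.ndarray, nA: int) -> float:
    """Exact two-sided p by enumeration of all assignments of size nA (midranks)."""
    n = len(values)
    ranks = rankdata(values)
    W_obs = ranks[:nA].sum()
    mu = nA * (n + 1) / 2.0
    dev = abs(W_obs - mu)
    hits = total = 0
    for combo in combinations(range(n), nA):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(a, b, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(W, p)`` with ``W`` the rank sum
    of the first sample. Exact when ``len(a)+len(b) <= exact_max_n``."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    values = np.concatenate([a, b])
    W = float(rankdata(values)[: a.size].sum())
    if values.size <= exact_max_n:
        p = _exact_p(values, a.size)
    else:
        p = _asymptotic_p(W, a.size, b.size, _tie_sum(values))
    return W, p


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_de(
    adata_or_matrix,
    group_a,
    group_b,
    genes=None,
    min_detected: int = 3,
    exact_max_n: int = EXACT_MAX_N,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum DE between two cell groups on log-normalized data.

    ``group_a``/``group_b`` are barcode collections (AnnData input) or row-index
    arrays (matrix input). Genes detected in fewer than ``min_detected`` cells across
    both groups are skipped. Returns a frame with ``gene, log2fc, statistic, p, fdr,
    n_a, n_b``; log2fc compares expm1 means with a small pseudocount.
    """
    if hasattr(adata_or_matrix, "obs_names"):
        adata = adata_or_matrix
        ia = adata.obs_names.isin(pd.Index(group_a))
        ib = adata.obs_names.isin(pd.Index(group_b))
        gene_names = np.asarray(adata.var_names)
        A = _dense(adata.X[ia])
        B = _dense(adata.X[ib])
    else:
        X = _dense(adata_or_matrix)
        A, B = X[np.asarray(group_a)], X[np.asarray(group_b)]
        gene_names = (np.asarray(genes) if genes is not None
                      else np.array([f"g{i}" for i in range(X.shape[1])]))
    nA, nB = A.shape[0], B.shape[0]
    if nA == 0 or nB == 0:
        raise ValueError("both groups must be nonempty")

    detected = (A > 0).sum(axis=0) + (B > 0).sum(axis=0)
    keep = detected >= min_detected
    if not keep.any():
        return pd.DataFrame(
            columns=["gene", "log2fc", "statistic", "p", "fdr", "n_a", "n_b"])
    A, B = A[:, keep], B[:, keep]
    names = gene_names[keep]
    stacked = np.vstack([A, B])
    n = nA + nB
    ranks = rankdata(stacked, axis=0)
    W = ranks[:nA].sum(axis=0)

    if n <= exact_max_n:
        mu = nA * (n + 1) / 2.0
        combos = np.array(list(combinations(range(n), nA)))
        # genes x assignments rank sums; two-sided tail at the observed deviation
        W_all = ranks.T[:, combos].sum(axis=2)
        dev = np.abs(W - mu)[:, None]
        p = (np.abs(W_all - mu) >= dev - 1e-9).mean(axis=1)
    else:
        mu = nA * (n + 1) / 2.0
        ties = np.array([_tie_sum(stacked[:, j]) for j in range(stacked.shape[1])])
        var = nA * nB / 12.0 * ((n + 1) - ties / (n * (n - 1)))
        z = np.zeros_like(W, dtype=float)
        ok = var > 0
        z[ok] = (W[ok] - mu) / np.sqrt(var[ok])
        p = np.where(ok, 2.0 * norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + LFC_PSEUDOCOUNT) / (mean_b + LFC_PSEUDOCOUNT))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": names, "log2fc": log2fc, "statistic": W.astype(float),
        "p": p, "fdr": fdr, "n_a": nA, "n_b": nB,
    })


def condition_genes(
    adata,
    fdr_max: float = 0.01,
    lfc_min: float = 0.5,
    condition_col: str = "condition",
    cell_type_col: str = "cell_type",
    min_cells: int = 20,
    n_top: int = 10,
):
    """Condition-related gene sets: per cell type, each condition's cells against all
    other conditions' cells of that type; genes up-regulated toward the condition
    (``fdr < fdr_max`` and ``log2fc > lfc_min``, log2 scale) are unioned per
    condition. The up-only direction keeps the sets condition-characteristic: under
    a one-vs-rest contrast a two-sided threshold would also place every gene into
    the conditions it is depleted from.

    Returns ``(sets, top_table, detail)``: per-condition sorted gene lists, the
    top-``n_top`` genes per condition ranked by minimum FDR then |log2fc|, and the
    full per-(condition, cell type) DE frame.
    """
    obs = adata.obs
    conditions = pd.unique(obs[condition_col])
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    frames = []
    for ctype in pd.unique(obs[cell_type_col]):
        sub = obs[obs[cell_type_col] == ctype]
        for cond in conditions:
            in_cond = sub.index[sub[condition_col] == cond]
            rest = sub.index[sub[condition_col] != cond]
            if len(in_cond) < min_cells or len(rest) < min_cells:
                log.info("skipping stratum (%s, %s): too few cells", ctype, cond)
                continue
            de = wilcoxon_de(adata, in_cond, rest)
            de.insert(0, "cell_type", ctype)
            de.insert(0, "condition", cond)
            frames.append(de)
    detail = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["condition", "cell_type", "gene", "log2fc",
                                         "statistic", "p", "fdr", "n_a", "n_b"]))
    hits = detail[(detail["fdr"] < fdr_max) & (detail["log2fc"] > lfc_min)]
    sets = {cond: sorted(hits.loc[hits["condition"] == cond, "gene"].unique())
            for cond in conditions}
    tops = []
    for cond in conditions:
        h = hits[hits["condition"] == cond].copy()
        if h.empty:
            continue
        h["abs_lfc"] = h["log2fc"].abs()
        agg = h.groupby("gene").agg(min_fdr=("fdr", "min"),
                                    max_abs_lfc=("abs_lfc", "max")).reset_index()
        agg = agg.sort_values(["min_fdr", "max_abs_lfc"],
                              ascending=[True, False]).head(n_top)
        agg.insert(0, "condition", cond)
        tops.append(agg)
    top_table = (pd.concat(tops, ignore_index=True) if tops
                 else pd.DataFrame(columns=["condition", "gene", "min_fdr", "max_abs_lfc"]))
    return sets, top_table, detail


def domain_clusters(clusters, conditions, threshold: float = 0.60) -> pd.DataFrame:
    """Classify clusters as condition 'domains' when one condition contributes at
    least ``threshold`` of the cluster's cells (inclusive); ties are not domains.

    Returns one row per nonempty cluster with the composition fractions, the
    dominant condition, and the domain flag.
    """
    clusters = pd.Series(np.asarray(clusters), name="cluster")
    conditions = pd.Series(np.asarray(conditions), name="condition")
    if len(clusters) != len(conditions):
        raise ValueError("clusters and conditions must align")
    df = pd.DataFrame({"cluster": clusters, "condition": conditions})
    rows = []
    for cid, grp in df.groupby("cluster", sort=True):
        frac = grp["condition"].value_counts(normalize=True)
        top = frac.iloc[0]
        tied = (frac >= top - 1e-12).sum() > 1
        is_domain = bool(top >= threshold - 1e-12) and not tied
        rows.append({
            "cluster": cid,
            "n_cells": len(grp),
            "composition": frac.to_dict(),
            "dominant_condition": None if tied else frac.index[0],
            "max_fraction": float(top),
            "is_domain": is_domain,
        })
    return pd.DataFrame(rows)
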