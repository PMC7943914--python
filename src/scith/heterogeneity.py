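"""Per-tumor transcriptomic diversity and per-cell-type transcriptional noise.

Diversity of a tumor is the mean Euclidean distance of the patient's malignant
cells to their centroid in the top principal components — a scale-bearing summary
of how spread out one tumor's cells are in expression space. Transcriptional noise
is the squared distance of each cell, over a panel of invariant genes (middle
expression decile, lowest coefficient of variation), to its (cell type, condition)
stratum mean; conditions are compared per cell type by rank-sum with BH adjustment.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .markers import rank_sum_test

log = logging.getLogger(__name__)

__all__ = ["diversity_score", "compare_diversity", "transcriptional_noise"]


def diversity_score(
    coordinates,
    annotation: pd.DataFrame,
    min_cells: int = 500,
    n_pcs: int = 10,
    malignant_col: str = "is_malignant",
    patient_col: str = "patient",
    condition_col: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient diversity scores over malignant cells in the top ``n_pcs`` PCs.

    ``coordinates`` is the cells x D PCA matrix aligned with ``annotation`` rows (an
    :class:`~scith.io_qc.Embedding` is accepted too). Patients with at most
    ``min_cells`` malignant cells are excluded and listed in the second frame.
    """
    if hasattr(coordinates, "coordinates"):
        coordinates = coordinates.coordinates
    P = np.asarray(coordinates, dtype=float)[:, :n_pcs]
    if len(annotation) != P.shape[0]:
        raise ValueError("annotation and coordinates must align")
    mal = annotation[malignant_col].astype(bool).to_numpy()
    rows, excluded = [], []
    for patient, grp in annotation.groupby(patient_col, sort=True, observed=True):
        idx = annotation.index.get_indexer(grp.index)
        mcells = idx[mal[idx]]
        cond = grp[condition_col].iloc[0]
        if len(mcells) <= min_cells:
            excluded.append({"patient": patient, "condition": cond,
                             "n_malignant_cells": len(mcells)})
            continue
        pts = P[mcells]
        centroid = pts.mean(axis=0)
        score = float(np.linalg.norm(pts - centroid, axis=1).mean())
        rows.append({"patient": patient, "condition": cond,
                     "n_malignant_cells": len(mcells), "score": score})
    if not rows:
        warnings.warn("no patient passes the malignant-cell inclusion rule",
                      stacklevel=2)
    cols = ["patient", "condition", "n_malignant_cells", "score"]
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(excluded, columns=cols[:3]))


def compare_diversity(
    scores: pd.DataFrame,
    group_a: str = "early",
    group_b: str = "advanced",
    condition_col: str = "condition",
) -> dict:
    """Two-sided rank-sum comparison of per-patient diversity between two conditions.

    Returns group means, the fold difference (mean b over mean a), and p; p is NaN
    (flagged) when either group has fewer than two patients.
    """
    a = scores.loc[scores[condition_col] == group_a, "score"].to_numpy()
    b = scores.loc[scores[condition_col] == group_b, "score"].to_numpy()
    out = {
        "group_a": group_a, "group_b": group_b,
        "n_a": int(a.size), "n_b": int(b.size),
        "mean_a": float(a.mean()) if a.size else np.nan,
        "mean_b": float(b.mean()) if b.size else np.nan,
    }
    out["fold"] = (out["mean_b"] / out["mean_a"]
                   if a.size and b.size and out["mean_a"] > 0 else np.nan)
    if a.size < 2 or b.size < 2:
        out["p"] = np.nan
        out["underpowered"] = True
    else:
        _, out["p"] = rank_sum_test(a, b)
        out["underpowered"] = False
    return out


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def invariant_gene_panel(
    adata,
    n_genes: int = 500,
    decile_band: tuple[float, float] = (0.45, 0.55),
) -> list:
    """Invariant genes: the middle mean-expression decile (quantile band centred on
    the median), ranked by lowest cross-cohort coefficient of variation."""
    X = adata.X
    if sparse.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = (np.asarray(X) ** 2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0)
    expressed = mean > 0
    lo, hi = np.quantile(mean[expressed], decile_band) if expressed.any() else (0, 0)
    cand = expressed & (mean >= lo) & (mean <= hi)
    if cand.sum() < n_genes:
        warnings.warn(
            f"only {int(cand.sum())} invariant-gene candidates for requested "
            f"{n_genes}; using all of them", stacklevel=2)
    cv = np.full(mean.shape, np.inf)
    cv[cand] = np.sqrt(var[cand]) / mean[cand]
    order = np.argsort(cv, kind="stable")
    chosen = [i for i in order[: min(n_genes, int(cand.sum()))]]
    return adata.var_names[np.sort(chosen)].tolist()


def transcriptional_noise(
    adata,
    invariant_genes: int = 500,
    equalize: bool = True,
    seed: int = 0,
    min_stratum: int = 20,
    cell_type_col: str = "cell_type",
    condition_col: str = "condition",
    compare: tuple[str, str] = ("early", "advanced"),
    fdr_max: float = 0.05,
    panel=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell transcriptional noise and the per-cell-type condition comparison.

    Noise of a cell is its squared Euclidean distance, over the invariant-gene
    panel, to the mean of its (cell type, condition) stratum. With ``equalize``,
    strata are downsampled to the smallest retained stratum before computing means
    (unequal n otherwise inflates the variance estimates), and noise is reported for
    the sampled cells. Strata below ``min_stratum`` cells are skipped and logged.

    Returns ``(noise_table, per_type)`` where ``per_type`` holds the rank-sum
    early-vs-advanced comparison with BH adjustment across cell types. ``panel``
    overrides the automatic invariant-gene selection with an explicit gene list.
    """
    if panel is None:
        panel = invariant_gene_panel(adata, n_genes=invariant_genes)
    X = _dense(adata[:, panel].X)
    obs = adata.obs
    strata = {}
    for key, grp in obs.groupby([cell_type_col, condition_col],
                                sort=True, observed=True):
        idx = obs.index.get_indexer(grp.index)
        if len(idx) < min_stratum:
            log.info("skipping stratum %s: %d cells < %d", key, len(idx), min_stratum)
            continue
        strata[key] = idx
    if not strata:
        raise ValueError("no (cell type, condition) stratum has enough cells")

    rng = np.random.default_rng(seed)
    if equalize:
        n_min = min(len(v) for v in strata.values())
        strata = {k: np.sort(rng.choice(v, size=n_min, replace=False))
                  for k, v in sorted(strata.items())}

    rows = []
    for (ctype, cond), idx in strata.items():
        sub = X[idx]
        centre = sub.mean(axis=0)
        noise = ((sub - centre) ** 2).sum(axis=1)
        for i, cell_i in enumerate(idx):
            rows.append((ctype, cond, obs.index[cell_i], float(noise[i])))
    noise_table = pd.DataFrame(
        rows, columns=["cell_type", "condition", "barcode", "noise"])

    a_lab, b_lab = compare
    per_type_rows = []
    for ctype in sorted({k[0] for k in strata}):
        a = noise_table.query("cell_type == @ctype and condition == @a_lab")["noise"]
        b = noise_table.query("cell_type == @ctype and condition == @b_lab")["noise"]
        if len(a) == 0 or len(b) == 0:
            continue
        _, p = rank_sum_test(a.to_numpy(), b.to_numpy())
        per_type_rows.append({
            "cell_type": ctype,
            f"median_{a_lab}": float(a.median()),
            f"median_{b_lab}": float(b.median()),
            "noise_ratio": float(b.median() / a.median()) if a.median() > 0 else np.inf,
            "p": p,
        })
    per_type = pd.DataFrame(per_type_rows)
    if len(per_type):
        per_type["fdr"] = multipletests(per_type["p"], method="fdr_bh")[1]
        per_type["significant"] = per_type["fdr"] < fdr_max
    else:
        per_type = per_type.reindex(columns=["cell_type", f"median_{a_lab}",
                                             f"median_{b_lab}", "noise_ratio",
                                             "p", "fdr", "significant"])
    return noise_table, per_type
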