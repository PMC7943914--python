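"""Gene-panel scoring per cell and per-cell-type metabolic pathway activity.

Panel scores are mean per-gene z-scores over the panel (constant genes contribute
zero), optionally aggregated per cluster. Pathway activity follows the
relative-mean construction standard for per-cell-type metabolic landscapes: for
each gene the linear-scale mean in a type is divided by the unweighted average of
all type means, and the pathway activity of a type is the mean of those ratios over
pathway genes — so every pathway's activity averages to 1 across types by
construction. Significance comes from cell-type label permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["GenePanel", "load_panels", "panel_score", "panel_scores",
           "cluster_panel_scores", "pathway_activity"]


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: tuple
    orientation: int = 1  # +1: high score = high expression; -1 flips the sign


def load_panels(path) -> list:
    """Read panels from a tidy TSV with columns ``panel``, ``gene`` and an optional
    ``orientation`` (+1/-1, constant per panel)."""
    df = pd.read_csv(path, sep="\t")
    if not {"panel", "gene"} <= set(df.columns):
        raise ValueError("panel table needs 'panel' and 'gene' columns")
    panels = []
    for name, grp in df.groupby("panel", sort=True):
        orient = int(grp["orientation"].iloc[0]) if "orientation" in grp else 1
        panels.append(GenePanel(name=name, genes=tuple(grp["gene"]), orientation=orient))
    return panels


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def panel_score(adata, panel: GenePanel) -> pd.Series | None:
    """Per-cell mean z-score over the panel genes present in the matrix.

    Returns ``None`` (with a warning) when no panel gene intersects the matrix.
    """
    genes = [g for g in panel.genes if g in adata.var_names]
    if not genes:
        warnings.warn(f"panel {panel.name!r} has no genes in the matrix; skipped",
                      stacklevel=2)
        return None
    X = _dense(adata[:, genes].X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(panel.orientation * Z.mean(axis=1),
                     index=adata.obs_names, name=panel.name)


def panel_scores(adata, panels) -> pd.DataFrame:
    """Score several panels; columns are panel names (skipped panels omitted)."""
    cols = {}
    for panel in panels:
        s = panel_score(adata, panel)
        if s is not None:
            cols[panel.name] = s
    return pd.DataFrame(cols, index=adata.obs_names)


def cluster_panel_scores(scores: pd.DataFrame, labels) -> pd.DataFrame:
    """Mean panel score per cluster (rows: cluster labels)."""
    labels = pd.Series(np.asarray(labels), index=scores.index, name="cluster")
    return scores.groupby(labels, observed=True).mean()


def pathway_activity(
    adata,
    gene_sets: dict,
    cell_type_col: str = "cell_type",
    n_perm: int = 1000,
    seed: int = 0,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Relative pathway activity per cell type with permutation significance.

    For each gene ``g``: ``r_g(t) = mean_t(g) / mean over types of type means``,
    computed on the linear (expm1 of log-normalized) scale; ``activity(P, t)`` is
    the mean of ``r_g(t)`` over pathway genes. ``p_up``/``p_down`` are upper- and
    lower-tail label-permutation p-values with the add-one correction.
    """
    obs = adata.obs
    types = sorted(obs[cell_type_col].astype(str).unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    all_genes = sorted({g for genes in gene_sets.values() for g in genes
                        if g in adata.var_names})
    usable = {}
    for name, genes in gene_sets.items():
        kept = [g for g in genes if g in adata.var_names]
        if kept:
            usable[name] = kept
        else:
            log.info("pathway %r has no genes in the matrix; skipped", name)
    if not usable:
        return pd.DataFrame(columns=["cell_type", "pathway", "activity",
                                     "p_up", "p_down"])

    E = np.expm1(_dense(adata[:, all_genes].X))
    labels = obs[cell_type_col].astype(str).to_numpy()
    col_of = {g: i for i, g in enumerate(all_genes)}

    def _activities(lab: np.ndarray) -> dict:
        means = np.vstack([E[lab == t].mean(axis=0) for t in types])
        denom = means.mean(axis=0)
        ok = denom > 0
        R = np.ones_like(means)
        R[:, ok] = means[:, ok] / denom[ok]
        out = {}
        for name, genes in usable.items():
            cols = [col_of[g] for g in genes]
            out[name] = R[:, cols].mean(axis=1)
        return out

    counts = pd.Series(labels).value_counts()
    if counts.min() < min_cells:
        raise ValueError("every cell type needs at least "
                         f"{min_cells} cells for stable means")
    obs_act = _activities(labels)
    rng = np.random.default_rng(int(seed) % (2**31))
    ge = {name: np.zeros(len(types)) for name in usable}
    le = {name: np.zeros(len(types)) for name in usable}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        act = _activities(perm)
        for name in usable:
            ge[name] += act[name] >= obs_act[name] - 1e-12
            le[name] += act[name] <= obs_act[name] + 1e-12
    rows = []
    for name in usable:
        for i, t in enumerate(types):
            rows.append({
                "cell_type": t, "pathway": name,
                "activity": float(obs_act[name][i]),
                "p_up": float((1 + ge[name][i]) / (1 + n_perm)),
                "p_down": float((1 + le[name][i]) / (1 + n_perm)),
            })
    return pd.DataFrame(rows)
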