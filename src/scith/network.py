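"""Per-condition cell-type transcriptome networks and per-stage marker signatures.

Each condition's network has one node per sufficiently large cell type carrying the
centroid (mean normalized expression over the highly variable genes); edges are
Pearson correlations between centroids over all type pairs, and the hub is the most
abundant type. Stage markers delegate to the Wilcoxon machinery with the stricter
up-regulation thresholds used for per-stage signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .markers import wilcoxon_de

log = logging.getLogger(__name__)

__all__ = ["TypeNetwork", "build_network", "stage_markers"]


@dataclass
class TypeNetwork:
    condition: str
    nodes: pd.DataFrame  # cell_type, n_cells
    centroids: pd.DataFrame  # cell types x HVGs
    hub: str
    edges: pd.DataFrame  # type_i, type_j, r (sorted by |r| descending)
    dropped: list = field(default_factory=list)


def build_network(
    adata,
    hvg=None,
    min_cells: int = 20,
    condition_col: str = "condition",
    cell_type_col: str = "cell_type",
) -> dict:
    """Build one :class:`TypeNetwork` per condition from log-normalized data.

    ``hvg`` defaults to ``adata.var['highly_variable']`` when present, else all
    genes. Cell types with fewer than ``min_cells`` cells in a condition are
    dropped and listed. Edges with an undefined correlation (a constant centroid)
    are recorded with ``r = NaN`` and a reason.
    """
    if hvg is None:
        if "highly_variable" in adata.var:
            hvg = adata.var_names[adata.var["highly_variable"]].tolist()
        else:
            hvg = adata.var_names.tolist()
    sub = adata[:, hvg]
    X = sub.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    obs = adata.obs
    out = {}
    for cond in pd.unique(obs[condition_col]):
        sel = obs[condition_col] == cond
        counts = obs.loc[sel, cell_type_col].value_counts()
        kept = counts[counts >= min_cells]
        dropped = counts[counts < min_cells].index.tolist()
        if len(kept) < 2:
            log.info("condition %r has < 2 usable cell types; skipped", cond)
            continue
        types = sorted(kept.index.tolist())
        centroids = np.vstack([
            X[(sel & (obs[cell_type_col] == t)).to_numpy()].mean(axis=0)
            for t in types])
        C = pd.DataFrame(centroids, index=types, columns=hvg)
        rows = []
        for i, ti in enumerate(types):
            for tj in types[i + 1:]:
                xi, xj = C.loc[ti].to_numpy(), C.loc[tj].to_numpy()
                if xi.std() == 0 or xj.std() == 0:
                    rows.append({"type_i": ti, "type_j": tj, "r": np.nan,
                                 "note": "constant centroid"})
                else:
                    rows.append({"type_i": ti, "type_j": tj,
                                 "r": float(np.corrcoef(xi, xj)[0, 1]), "note": ""})
        edges = pd.DataFrame(rows)
        edges = edges.iloc[np.argsort(-edges["r"].abs().fillna(-np.inf).to_numpy(),
                                      kind="stable")].reset_index(drop=True)
        out[cond] = TypeNetwork(
            condition=cond,
            nodes=pd.DataFrame({"cell_type": types,
                                "n_cells": [int(kept[t]) for t in types]}),
            centroids=C,
            hub=kept.idxmax(),
            edges=edges,
            dropped=dropped,
        )
    return out


def stage_markers(
    adata,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    stage_col: str = "condition",
) -> dict:
    """Up-regulated marker genes per stage: each stage's cells against all others,
    filtered at ``log2fc > lfc_min`` (strict) and ``fdr < fdr_max`` (strict)."""
    obs = adata.obs
    out = {}
    for stage in pd.unique(obs[stage_col]):
        in_stage = obs.index[obs[stage_col] == stage]
        rest = obs.index[obs[stage_col] != stage]
        if len(in_stage) == 0 or len(rest) == 0:
            continue
        de = wilcoxon_de(adata, in_stage, rest)
        out[stage] = de[(de["log2fc"] > lfc_min) & (de["fdr"] < fdr_max)] \
            .sort_values("fdr").reset_index(drop=True)
    return out
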