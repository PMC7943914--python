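"""Condition-stratified ligand-receptor interaction calling (CellTalker-style rule).

A gene counts as expressed by a cell type in a condition when, in strictly more
than half of that condition's patients, it is detected (raw count > 0) in strictly
more than ``min_cells`` cells of that type. An interaction is called for
(ligand, receptor, sender, receiver) in a condition when the ligand passes the rule
in the sender type and the receptor in the receiver type. Across conditions the
called tuples partition into *unique* (exactly one condition) and *common*
(two or more); tuples present in three or more conditions are additionally visible
through the ``n_conditions`` column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["load_lr_pairs", "expressed_in", "call_interactions", "summarize_interactions"]


def load_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand-receptor pair table (CSV with ``ligand``/``receptor`` columns)."""
    df = pd.read_csv(path)
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise ValueError(f"LR pair table lacks columns: {sorted(missing)}")
    df = df[df["ligand"] != df["receptor"]].drop_duplicates(["ligand", "receptor"])
    return df.reset_index(drop=True)


def _counts_matrix(adata):
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return X if sparse.issparse(X) else sparse.csr_matrix(X)


def _detection_table(adata, genes, patient_col, cell_type_col, condition_col):
    """Rows: (condition, patient, cell_type); columns: genes; values: number of
    cells of that type with a nonzero raw count."""
    gidx = [adata.var_names.get_loc(g) for g in genes]
    X = _counts_matrix(adata)[:, gidx]
    det = (X > 0).astype(np.int64)
    obs = adata.obs
    keys = obs[[condition_col, patient_col, cell_type_col]].astype(str)
    rows = []
    index = []
    for key, grp in keys.groupby([condition_col, patient_col, cell_type_col],
                                 sort=True, observed=True):
        idx = obs.index.get_indexer(grp.index)
        rows.append(np.asarray(det[idx].sum(axis=0)).ravel())
        index.append(key)
    return pd.DataFrame(rows, columns=list(genes),
                        index=pd.MultiIndex.from_tuples(
                            index, names=[condition_col, patient_col, cell_type_col]))


def expressed_in(
    adata,
    gene: str,
    cell_type: str,
    condition: str,
    min_cells: int = 10,
    min_patient_frac: float = 0.5,
    patient_col: str = "patient",
    cell_type_col: str = "cell_type",
    condition_col: str = "condition",
) -> tuple[bool, int, int]:
    """Apply the detection rule for one (gene, cell type, condition).

    Returns ``(expressed, n_qualifying_patients, n_patients_in_condition)``. A
    patient with no cells of the type counts as non-qualifying.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent from the matrix")
    obs = adata.obs
    in_cond = obs[condition_col].astype(str) == str(condition)
    patients = sorted(obs.loc[in_cond, patient_col].astype(str).unique())
    if not patients:
        return False, 0, 0
    gi = adata.var_names.get_loc(gene)
    col = np.asarray((_counts_matrix(adata)[:, [gi]] > 0).todense()).ravel()
    qualifying = 0
    for patient in patients:
        sel = (in_cond & (obs[patient_col].astype(str) == patient)
               & (obs[cell_type_col].astype(str) == str(cell_type))).to_numpy()
        if col[sel].sum() > min_cells:  # strictly more than min_cells cells
            qualifying += 1
    expressed = qualifying / len(patients) > min_patient_frac  # strict majority
    return bool(expressed), qualifying, len(patients)


def call_interactions(
    adata,
    pairs: pd.DataFrame,
    min_cells: int = 10,
    min_patient_frac: float = 0.5,
    patient_col: str = "patient",
    cell_type_col: str = "cell_type",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Call interactions for every (pair, sender, receiver, condition) combination.

    Returns the interaction table with columns ``condition, ligand, receptor,
    sender, receiver, n_supporting_patients_sender, n_supporting_patients_receiver,
    n_patients, n_conditions, interaction_class``. Pairs whose genes are absent
    from the matrix are skipped and logged. Deterministic given the counts.
    """
    if pairs.empty:
        return pd.DataFrame(columns=[
            "condition", "ligand", "receptor", "sender", "receiver",
            "n_supporting_patients_sender", "n_supporting_patients_receiver",
            "n_patients", "n_conditions", "interaction_class"])
    present = set(adata.var_names)
    usable = pairs[pairs["ligand"].isin(present) & pairs["receptor"].isin(present)]
    skipped = len(pairs) - len(usable)
    if skipped:
        log.info("skipping %d LR pairs with genes absent from the matrix", skipped)
    genes = sorted(set(usable["ligand"]) | set(usable["receptor"]))
    if not genes:
        return call_interactions(adata, pairs.iloc[0:0])

    det = _detection_table(adata, genes, patient_col, cell_type_col, condition_col)
    obs = adata.obs
    conditions = sorted(obs[condition_col].astype(str).unique())
    records = []
    for cond in conditions:
        cond_obs = obs[obs[condition_col].astype(str) == cond]
        patients = sorted(cond_obs[patient_col].astype(str).unique())
        types = sorted(cond_obs[cell_type_col].astype(str).unique())
        n_pat = len(patients)
        # expressed[(type, gene)] -> number of qualifying patients
        support = {}
        for ctype in types:
            for gene in genes:
                n_q = 0
                for patient in patients:
                    key = (cond, patient, ctype)
                    n_det = det.loc[key, gene] if key in det.index else 0
                    if n_det > min_cells:
                        n_q += 1
                support[(ctype, gene)] = n_q
        thresh = min_patient_frac * n_pat
        for _, row in usable.iterrows():
            for sender in types:
                ns = support[(sender, row["ligand"])]
                if not ns > thresh:
                    continue
                for receiver in types:
                    nr = support[(receiver, row["receptor"])]
                    if not nr > thresh:
                        continue
                    records.append({
                        "condition": cond, "ligand": row["ligand"],
                        "receptor": row["receptor"], "sender": sender,
                        "receiver": receiver,
                        "n_supporting_patients_sender": ns,
                        "n_supporting_patients_receiver": nr,
                        "n_patients": n_pat,
                    })
    table = pd.DataFrame(records)
    if table.empty:
        return call_interactions(adata, pairs.iloc[0:0])
    key_cols = ["ligand", "receptor", "sender", "receiver"]
    n_cond = table.groupby(key_cols)["condition"].transform("nunique")
    table["n_conditions"] = n_cond
    table["interaction_class"] = np.where(n_cond == 1, "unique", "common")
    return table.sort_values(["condition"] + key_cols).reset_index(drop=True)


def summarize_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition counts of unique and common interaction calls."""
    if table.empty:
        return pd.DataFrame(columns=["condition", "n_unique", "n_common", "n_total"])
    rows = []
    for cond, grp in table.groupby("condition", sort=True):
        rows.append({
            "condition": cond,
            "n_unique": int((grp["interaction_class"] == "unique").sum()),
            "n_common": int((grp["interaction_class"] == "common").sum()),
            "n_total": len(grp),
        })
    return pd.DataFrame(rows)
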