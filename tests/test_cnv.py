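"""CNV inference: smoothing identities, null behaviour, planted-segment recovery,
and the malignancy score/flag rule."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from scith import cnv, io_qc, simulate

REF_TYPES = ("T_cell", "B_cell", "myeloid", "fibroblast")


def _adata_from_matrix(X, chrom=None):
    n_cells, n_genes = X.shape
    var = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n_genes,
        "ordinal": np.arange(n_genes),
    }, index=[f"G{i}" for i in range(n_genes)])
    return ad.AnnData(X=np.asarray(X, dtype=float),
                      obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
                      var=var)


def test_window_one_is_identity_smoothing():
    """window=1 returns the clipped, median-recentred log2 ratio exactly, and the
    resulting score is invariant to gene-order permutation."""
    rng = np.random.default_rng(0)
    X = rng.normal(2.0, 0.3, size=(40, 60))
    adata = _adata_from_matrix(X)
    ref = [f"c{i}" for i in range(30)]
    prof = cnv.infer_cnv(adata, ref, window=1, clip=3.0, min_mean=0.0)
    manual = (X - X[:30].mean(axis=0)) / np.log(2.0)
    manual = np.clip(manual, -3, 3)
    manual -= np.median(manual, axis=1, keepdims=True)
    np.testing.assert_allclose(prof.matrix, manual, atol=1e-12)

    perm = rng.permutation(60)
    adata_p = _adata_from_matrix(X[:, perm])
    adata_p.var["ordinal"] = np.arange(60)
    prof_p = cnv.infer_cnv(adata_p, ref, window=1, clip=3.0, min_mean=0.0)
    s1 = cnv.malignancy_score(prof).scores.to_numpy()
    s2 = cnv.malignancy_score(prof_p).scores.to_numpy()
    np.testing.assert_allclose(s1, s2, atol=1e-12)


def test_score_closed_forms():
    """Zero profile scores 0 everywhere with no flags; a constant profile value c
    scores exactly c^2."""
    prof = cnv.CnvProfile(
        matrix=np.zeros((5, 20)), genes=[f"G{i}" for i in range(20)],
        gene_order=pd.DataFrame(), barcodes=[f"c{i}" for i in range(5)],
        reference_cells=["c0", "c1"], window=1, clip=3.0, dropped_genes=[])
    ms = cnv.malignancy_score(prof)
    assert (ms.scores == 0).all() and not ms.flags.any()

    prof.matrix = np.vstack([np.zeros((4, 20)), np.full((1, 20), 0.7)])
    ms = cnv.malignancy_score(prof)
    assert ms.scores.iloc[-1] == pytest.approx(0.49, abs=1e-12)


def test_null_data_reference_and_query_comparable():
    """With all cells identically distributed, non-reference profiles are no more
    extreme than reference profiles (within 2x), and median scores are similar."""
    rng = np.random.default_rng(3)
    X = rng.normal(1.5, 0.4, size=(200, 300))
    adata = _adata_from_matrix(X, chrom=["chr1"] * 150 + ["chr2"] * 150)
    ref = [f"c{i}" for i in range(100)]
    prof = cnv.infer_cnv(adata, ref, window=31, min_mean=0.0)
    ref_mask = np.arange(200) < 100
    m_ref = np.abs(prof.matrix[ref_mask]).mean()
    m_query = np.abs(prof.matrix[~ref_mask]).mean()
    assert m_query <= 2.0 * m_ref
    ms = cnv.malignancy_score(prof)
    med_ref = ms.scores[ref_mask].median()
    med_query = ms.scores[~ref_mask].median()
    assert med_ref <= med_query * 1.5


def test_too_few_reference_cells_rejected():
    X = np.ones((40, 50)) + np.random.default_rng(0).normal(0, 0.1, (40, 50))
    adata = _adata_from_matrix(X)
    with pytest.raises(ValueError, match="reference cells"):
        cnv.infer_cnv(adata, ["c0", "c1"], min_mean=0.0)


@pytest.fixture(scope="module")
def cnv_cohort():
    cfg = simulate.default_config(seed=21, n_cells_per_patient=250, n_genes=1000)
    adata, gt = simulate.simulate_cohort(cfg)
    adata, _ = io_qc.apply_qc(adata)
    io_qc.normalize_log(adata)
    ref = adata.obs_names[adata.obs["cell_type"].isin(REF_TYPES)].tolist()
    prof = cnv.infer_cnv(adata, ref)
    return adata, gt, prof


def test_planted_segment_exceeds_background(cnv_cohort):
    """Mean smoothed value inside a planted +1 segment exceeds the 99th percentile
    of outside-segment values for that patient's malignant cells."""
    adata, gt, prof = cnv_cohort
    pos = {g: i for i, g in enumerate(prof.genes)}
    patient = sorted(gt.cnv_segments)[0]
    seg = next(s for s in gt.cnv_segments[patient] if s["log2_dosage"] == 1.0)
    cells = np.nonzero((adata.obs["patient"] == patient).to_numpy()
                       & adata.obs["is_malignant"].to_numpy())[0]
    seg_genes = [pos[g] for g in adata.var_names[seg["start_index"]:seg["end_index"]]
                 if g in pos]
    # smoothing spreads a segment across its chromosome, so the clean background
    # is the set of chromosomes without any planted segment for this patient
    seg_chroms = {s["chrom"] for s in gt.cnv_segments[patient]}
    chrom_arr = prof.gene_order["chrom"].to_numpy()
    outside = [i for i in range(len(prof.genes)) if chrom_arr[i] not in seg_chroms]
    inside_mean = prof.matrix[np.ix_(cells, seg_genes)].mean()
    outside_q99 = np.quantile(prof.matrix[np.ix_(cells, outside)], 0.99)
    assert inside_mean > outside_q99


def test_malignancy_flags_recover_planted_cells(cnv_cohort):
    """Flags reach precision and recall >= 0.9 against the planted ledger."""
    adata, _, prof = cnv_cohort
    ms = cnv.malignancy_score(prof)
    truth = adata.obs["is_malignant"].to_numpy()
    flag = ms.flags.to_numpy()
    tp = (truth & flag).sum()
    precision = tp / max(flag.sum(), 1)
    recall = tp / truth.sum()
    assert precision >= 0.9 and recall >= 0.9


def test_dosage_monotonicity():
    """Doubling the planted dosage magnitude never decreases the median malignant
    score (paired seeds)."""
    meds = []
    for dosage in (0.58, 1.16):
        cfg = simulate.default_config(
            seed=17, conditions=("n", "t"), n_patients_per_condition=1,
            n_cells_per_patient=300, n_genes=600,
            cell_types=("cancer", "T_cell", "myeloid"),
            dispersion={"n": 0.1, "t": 0.1}, with_lr=False)
        cfg.cnv_segments = {"t_p1": [simulate.CnvSegment("chr1", 20, 90, dosage)]}
        adata, _ = simulate.simulate_cohort(cfg)
        adata, _ = io_qc.apply_qc(adata)
        io_qc.normalize_log(adata)
        ref = adata.obs_names[adata.obs["cell_type"].isin(REF_TYPES)].tolist()
        prof = cnv.infer_cnv(adata, ref)
        ms = cnv.malignancy_score(prof)
        meds.append(ms.scores[adata.obs["is_malignant"].to_numpy()].median())
    assert meds[1] >= meds[0]
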