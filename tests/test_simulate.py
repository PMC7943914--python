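"""Generator correctness: null model, planted effects, determinism, fixture I/O."""

import numpy as np
import pandas as pd
import pytest

from scith import simulate


def _null_config(seed=0, n_cells=600, n_genes=300):
    """Single-type, effect-free, Poisson, fixed-libsize configuration."""
    cfg = simulate.default_config(
        seed=seed, conditions=("only",), n_patients_per_condition=1,
        n_cells_per_patient=n_cells, n_genes=n_genes,
        cell_types=("T_cell",), dispersion={"only": 0.0},
        with_cnv=False, with_lr=False,
        n_type_markers=0, n_condition_de=0,
        low_depth_cell_fraction=0.0, high_mito_cell_fraction=0.0,
        libsize_lognormal=(0.0, 0.0),
    )
    return cfg


def test_null_model_means_match_base_expression():
    """With all effects zero, dispersion 0, and fixed library size, empirical
    per-gene means equal base_expression within Poisson sampling error."""
    cfg = _null_config()
    adata, _ = simulate.simulate_cohort(cfg)
    emp = np.asarray(adata.X.mean(axis=0)).ravel()
    base = np.asarray(cfg.base_expression)
    # Poisson SE of the mean = sqrt(mu/n); allow 5 SEs plus a small floor
    se = np.sqrt(base / adata.n_obs)
    assert np.all(np.abs(emp - base) < 5 * se + 0.02)


def test_planted_cnv_segment_doubles_group_means():
    """A +1 log2-dosage segment doubles malignant-cell mean counts on the
    segment genes relative to matched normal cells."""
    cfg = simulate.default_config(
        seed=5, conditions=("n", "t"), n_patients_per_condition=1,
        n_cells_per_patient=600, n_genes=400,
        cell_types=("cancer", "T_cell"), dispersion={"n": 0.05, "t": 0.05},
        with_lr=False, n_condition_de=0, n_type_markers=0,
        low_depth_cell_fraction=0.0, high_mito_cell_fraction=0.0,
    )
    seg = simulate.CnvSegment("chr1", 100, 300, 1.0)
    cfg.cnv_segments = {"t_p1": [seg]}
    adata, _ = simulate.simulate_cohort(cfg)
    X = adata.X.toarray()
    mal = adata.obs["is_malignant"].to_numpy()
    sl = slice(seg.start_index, seg.end_index)
    m_mal = X[mal][:, sl].mean()
    m_norm = X[~mal][:, sl].mean()
    assert m_mal / m_norm == pytest.approx(2.0, rel=0.1)
    # genes outside the segment are unaffected
    out = np.r_[0:100, 300:400]
    assert X[mal][:, out].mean() / X[~mal][:, out].mean() == pytest.approx(1.0, rel=0.1)


def test_same_seed_same_mtx_bytes(tmp_path):
    """Identical config and seed produce byte-identical MTX output."""
    outputs = []
    for name in ("a", "b"):
        cfg = simulate.default_config(seed=42, n_patients_per_condition=1,
                                      n_cells_per_patient=50, n_genes=200)
        adata, gt = simulate.simulate_cohort(cfg)
        d = tmp_path / name
        simulate.write_fixture(adata, gt, d)
        outputs.append((d / "matrix.mtx").read_bytes())
    assert outputs[0] == outputs[1]


def test_overdispersion_exceeds_poisson():
    """Per-gene variance exceeds the mean when dispersion > 0 (>= 500 cells)."""
    cfg = _null_config(seed=7, n_cells=800)
    cfg.dispersion = {"only": 0.4}
    adata, _ = simulate.simulate_cohort(cfg)
    X = adata.X.toarray()
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    strong = mean > 1.0  # overdispersion is detectable on expressed genes
    assert (var[strong] > mean[strong]).mean() > 0.95


def test_fixture_roundtrip_and_labels(tmp_path):
    """Round-trip read equals the in-memory object; annotation carries exactly
    the simulated condition labels; manifest lists the six fixture files."""
    cfg = simulate.default_config(seed=3, n_patients_per_condition=1,
                                  n_cells_per_patient=10, n_genes=120)
    adata, gt = simulate.simulate_cohort(cfg)
    manifest = simulate.write_fixture(adata, gt, tmp_path / "fx")
    assert len(manifest) == 6
    back, gt2 = simulate.read_fixture(tmp_path / "fx")
    assert (back.X != adata.X).nnz == 0
    assert back.obs_names.tolist() == adata.obs_names.tolist()
    annot = pd.read_csv(tmp_path / "fx" / "annotation.tsv", sep="\t")
    assert sorted(annot["condition"].unique()) == sorted(cfg.conditions)
    assert gt2.cnv_segments.keys() == gt.cnv_segments.keys()


def test_empty_cohort_writes_valid_fixture(tmp_path):
    """A zero-cell cohort still writes a valid (empty) fixture of six files."""
    cfg = simulate.default_config(seed=0, n_patients_per_condition=1,
                                  n_cells_per_patient=0, n_genes=100)
    adata, gt = simulate.simulate_cohort(cfg)
    assert adata.n_obs == 0
    manifest = simulate.write_fixture(adata, gt, tmp_path / "empty")
    assert len(manifest) == 6
    back, _ = simulate.read_fixture(tmp_path / "empty")
    assert back.n_obs == 0 and back.n_vars == 100


def test_ground_truth_ledger_covers_all_plants(cohort):
    """Every planted entity is recoverable from the ledger by identifier."""
    adata, gt, cfg = cohort
    genes = set(adata.var_names)
    for cond in cfg.conditions:
        planted = gt.de_genes(cond)
        assert planted and planted <= genes
    for t in cfg.cell_types:
        assert gt.marker_genes(t) <= genes
    for patient in gt.cnv_segments:
        dv = gt.dosage_vector(patient)
        assert dv.shape == (cfg.n_genes,) and np.any(dv != 0)
    assert gt.planted_lr() and gt.decoy_lr()
    mito = [g for g in genes if g.startswith("MT-")]
    assert sorted(gt.mito_genes) == sorted(mito)
    # effect sets never touch the mitochondrial block
    for cond in cfg.conditions:
        assert not gt.de_genes(cond) & set(mito)


def test_inconsistent_config_rejected():
    cfg = simulate.default_config(seed=0, n_genes=100,
                                  n_patients_per_condition=1,
                                  n_cells_per_patient=10)
    cfg.base_expression = np.ones(50)  # wrong length
    with pytest.raises(simulate.SimConfigError):
        simulate.simulate_cohort(cfg)
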