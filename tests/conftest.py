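"""Shared fixtures: one mid-size synthetic cohort, prepared once per session."""

import warnings

import numpy as np
import pytest

from scith import heterogeneity  # noqa: F401 - imported for warning registration
from scith import io_qc, simulate


@pytest.fixture(scope="session")
def cohort():
    """Raw mid-size cohort (3 conditions x 3 patients x 250 cells, 1000 genes)."""
    cfg = simulate.default_config(
        seed=11, n_cells_per_patient=250, n_genes=1000)
    adata, gt = simulate.simulate_cohort(cfg)
    return adata, gt, cfg


@pytest.fixture(scope="session")
def prepared(cohort):
    """QC'd, log-normalized, embedded view of the session cohort."""
    adata, gt, cfg = cohort
    adata = adata.copy()
    adata, report = io_qc.apply_qc(adata)
    io_qc.normalize_log(adata)
    emb = io_qc.select_hvg_and_pca(adata, n_hvg=500, n_pcs=30)
    return adata, gt, emb, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="only .* invariant-gene candidates")
        yield
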