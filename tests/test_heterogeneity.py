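"""Diversity-score geometry and calibration; transcriptional-noise behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import anndata as ad
from scith import heterogeneity, io_qc, simulate


def _annotation(patients, conditions, malignant):
    return pd.DataFrame({
        "patient": patients, "condition": conditions, "is_malignant": malignant,
    }, index=[f"c{i}" for i in range(len(patients))])


def test_degenerate_cloud_scores_zero():
    """All of a patient's malignant cells at one point give score 0."""
    P = np.zeros((40, 10))
    annot = _annotation(["p1"] * 40, ["early"] * 40, [True] * 40)
    div, _ = heterogeneity.diversity_score(P, annot, min_cells=10)
    assert div["score"].iloc[0] == 0.0


def test_isotropic_gaussian_matches_analytic_constant(rng):
    """Mean distance-to-centroid of N(0, sigma^2 I_d) is
    sigma * sqrt(2) * Gamma((d+1)/2) / Gamma(d/2) (times the sqrt((n-1)/n)
    centroid-estimation shrinkage); d=10 gives ~3.0844 sigma."""
    d, n, sigma = 10, 100_000, 1.7
    expected_unit = np.sqrt(2.0) * np.exp(gammaln((d + 1) / 2) - gammaln(d / 2))
    assert expected_unit == pytest.approx(3.0844, abs=2e-4)
    P = rng.normal(0.0, sigma, size=(n, d))
    annot = _annotation(["p1"] * n, ["early"] * n, [True] * n)
    div, _ = heterogeneity.diversity_score(P, annot, min_cells=10)
    expected = sigma * expected_unit * np.sqrt((n - 1) / n)
    assert div["score"].iloc[0] == pytest.approx(expected, rel=0.02)


def test_diversity_invariant_to_rigid_motion(rng):
    """Translation and rotation of the embedding leave the score unchanged."""
    P = rng.normal(size=(200, 10))
    annot = _annotation(["p1"] * 200, ["early"] * 200, [True] * 200)
    base = heterogeneity.diversity_score(P, annot, min_cells=10)[0]["score"].iloc[0]
    Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
    moved = P @ Q + 42.0
    other = heterogeneity.diversity_score(moved, annot, min_cells=10)[0]["score"].iloc[0]
    assert other == pytest.approx(base, abs=1e-9)


def test_inclusion_rule_and_empty_warning():
    """Patients at or below min_cells malignant cells are excluded and listed."""
    P = np.random.default_rng(0).normal(size=(30, 10))
    annot = _annotation(["p1"] * 10 + ["p2"] * 20,
                        ["early"] * 10 + ["advanced"] * 20,
                        [True] * 30)
    div, excluded = heterogeneity.diversity_score(P, annot, min_cells=10)
    assert div["patient"].tolist() == ["p2"]
    assert excluded["patient"].tolist() == ["p1"]
    with pytest.warns(UserWarning, match="no patient"):
        heterogeneity.diversity_score(P, annot, min_cells=1000)


def test_compare_diversity_exact_p_and_symmetry():
    """{1,2,3} vs {4,5,6} gives exact p = 0.1; identical multisets give p = 1;
    swapping the groups inverts the fold and keeps p."""
    scores = pd.DataFrame({
        "condition": ["early"] * 3 + ["advanced"] * 3,
        "score": [1, 2, 3, 4, 5, 6],
    })
    res = heterogeneity.compare_diversity(scores)
    assert res["p"] == pytest.approx(0.1, abs=1e-12)
    swapped = heterogeneity.compare_diversity(scores, group_a="advanced",
                                              group_b="early")
    assert swapped["p"] == pytest.approx(res["p"])
    assert swapped["fold"] == pytest.approx(1.0 / res["fold"])

    same = pd.DataFrame({"condition": ["early"] * 3 + ["advanced"] * 3,
                         "score": [1, 2, 3, 1, 2, 3]})
    assert heterogeneity.compare_diversity(same)["p"] == pytest.approx(1.0)

    tiny = pd.DataFrame({"condition": ["early", "advanced"], "score": [1, 2]})
    out = heterogeneity.compare_diversity(tiny)
    assert np.isnan(out["p"]) and out["underpowered"]


def test_planted_dispersion_orders_diversity():
    """Three synthetic tumors with dispersion multipliers 1x/2x/3x produce
    strictly increasing diversity scores."""
    cfg = simulate.default_config(
        seed=8, conditions=("d1", "d2", "d3"), n_patients_per_condition=1,
        n_cells_per_patient=300, n_genes=600, cell_types=("cancer",),
        dispersion={"d1": 0.1, "d2": 0.2, "d3": 0.3},
        with_cnv=False, with_lr=False,
        low_depth_cell_fraction=0.0, high_mito_cell_fraction=0.0)
    adata, _ = simulate.simulate_cohort(cfg)
    io_qc.normalize_log(adata)
    emb = io_qc.select_hvg_and_pca(adata, n_hvg=400, n_pcs=20)
    div, _ = heterogeneity.diversity_score(emb, adata.obs, min_cells=100)
    s = div.set_index("condition")["score"]
    assert s["d1"] < s["d2"] < s["d3"]


# --------------------------------------------------------------------------- noise


def test_identical_cells_have_zero_noise():
    X = np.tile(np.arange(1.0, 21.0), (50, 1))
    X[:, 0] = np.linspace(0.5, 1.5, 50)  # one variable gene so HVG paths are sane
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"cell_type": ["t"] * 50,
                          "condition": ["early"] * 25 + ["advanced"] * 25},
                         index=[f"c{i}" for i in range(50)]))
    with pytest.warns(UserWarning):
        noise, per_type = heterogeneity.transcriptional_noise(
            adata, invariant_genes=5, min_stratum=10)
    # invariant genes come from the constant middle-decile block -> zero noise
    assert (noise["noise"] <= 1e-12).all()


def test_noise_invariant_to_constant_gene(prepared):
    """Adding an all-constant gene to the invariant set leaves noise unchanged
    (zero-variance genes contribute nothing to the distance)."""
    adata = prepared[0]
    sub = adata[:, list(adata.var_names[:300])].copy()
    panel = heterogeneity.invariant_gene_panel(sub, n_genes=40)
    n1, _ = heterogeneity.transcriptional_noise(sub, seed=7, panel=panel)
    const = ad.AnnData(
        X=np.hstack([sub.X.toarray(), np.full((sub.n_obs, 1), 3.3)]),
        obs=sub.obs.copy(),
        var=pd.DataFrame(index=list(sub.var_names) + ["CONST"]))
    n2, _ = heterogeneity.transcriptional_noise(const, seed=7,
                                                panel=panel + ["CONST"])
    merged = n1.merge(n2, on=["cell_type", "condition", "barcode"])
    np.testing.assert_allclose(merged["noise_x"], merged["noise_y"], atol=1e-9)


def test_planted_dispersion_raises_noise_everywhere(prepared):
    """3x dispersion in the advanced condition lifts the median noise of every
    cell type, with BH-adjusted p < 0.05."""
    adata = prepared[0]
    _, per_type = heterogeneity.transcriptional_noise(
        adata, invariant_genes=120, seed=0)
    assert len(per_type) >= 5
    assert per_type["significant"].all()
    assert (per_type["noise_ratio"] > 1).all()


def test_label_permutation_kills_noise_flags(prepared):
    """Permuting condition labels leaves no significant cell types in the vast
    majority of runs (flag count within the exact binomial(runs, 5%) bound)."""
    from scipy.stats import binom

    adata = prepared[0].copy()
    rng = np.random.default_rng(99)
    hits = 0
    runs = 20
    panel = heterogeneity.invariant_gene_panel(adata, n_genes=120)
    for _ in range(runs):
        perm = adata.obs["condition"].sample(
            frac=1.0, random_state=int(rng.integers(2**31))).to_numpy()
        shuffled = adata.copy()
        shuffled.obs["condition"] = perm
        _, per_type = heterogeneity.transcriptional_noise(
            shuffled, seed=0, panel=panel)
        hits += int(per_type["significant"].any())
    assert hits <= binom.ppf(0.99, runs, 0.05)
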