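"""PGLS machinery, allometry classification, BH correction, size proxy."""

import math

import dendropy
import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from trabec.comparative import SimulationSpec, simulate_comparative_dataset, simulate_tree
from trabec.stats import (
    TRAIT_DIMENSIONS,
    allometry_test,
    bh_adjust,
    dataset_summary,
    isometric_exponent,
    lifestyle_pairwise,
    pgls_fit,
    phylo_covariance,
    validate_size_proxy,
)


# ------------------------------------------------------- isometric exponents


@pytest.mark.parametrize("dim,expected", [(-3, -3.0), (-1, -1.0), (0, 0.0), (1, 1.0)])
def test_isometric_exponent_equals_trait_dimension(dim, expected):
    assert isometric_exponent(dim) == expected


def test_isometric_exponent_rejects_unknown_dimension():
    with pytest.raises(ValueError, match="dimension"):
        isometric_exponent(2)


def test_trait_dimension_table_covers_all_six_parameters():
    assert set(TRAIT_DIMENSIONS) == {"BVTV", "DA", "TbTh", "TbSp", "BSBV", "ConnD"}


# ------------------------------------------------------- covariance


def test_covariance_lambda_zero_is_diagonal():
    tree = simulate_tree(12, seed=0)
    V, taxa = phylo_covariance(tree, 0.0)
    assert np.allclose(V, np.diag(np.diag(V)))
    assert np.allclose(np.diag(V), 1.0)  # unit-height tree


def test_covariance_cherry_from_root_has_no_shared_path():
    tree = dendropy.Tree.get(data="(A:0.4,B:0.9);", schema="newick")
    for lam in (0.0, 0.5, 1.0):
        V, taxa = phylo_covariance(tree, lam, ["A", "B"])
        np.testing.assert_allclose(V, [[0.4, 0], [0, 0.9]])


def test_covariance_balanced_tree_matches_hand_computed_paths():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    V, taxa = phylo_covariance(tree, 1.0, ["A", "B", "C", "D"])
    expected = np.array(
        [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]], dtype=float
    )
    np.testing.assert_allclose(V, expected)
    V5, _ = phylo_covariance(tree, 0.5, ["A", "B", "C", "D"])
    np.testing.assert_allclose(V5, np.where(np.eye(4, dtype=bool), expected, expected * 0.5))


def test_covariance_rejects_negative_branch_lengths():
    tree = dendropy.Tree.get(data="(A:1,B:-0.5);", schema="newick")
    with pytest.raises(ValueError, match="negative"):
        phylo_covariance(tree, 1.0)


# ------------------------------------------------------- PGLS


def test_pgls_lambda_zero_equals_ols_exactly():
    tree = simulate_tree(20, seed=3)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    y = 1 + 2 * x + rng.normal(size=20) * 0.5
    X = np.column_stack([np.ones(20), x])
    fit = pgls_fit(y, X, tree, taxa, lam=0.0)
    ols = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.params, ols.params, rtol=0, atol=1e-12)
    np.testing.assert_allclose(fit.bse, ols.bse, rtol=0, atol=1e-12)
    np.testing.assert_allclose(fit.pvalues, ols.pvalues, rtol=0, atol=1e-12)


def test_pgls_star_tree_lambda_one_equals_ols():
    taxa = [f"t{i}" for i in range(15)]
    newick = "(" + ",".join(f"{t}:1.0" for t in taxa) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(1)
    x = rng.normal(size=15)
    y = 0.3 - 1.2 * x + rng.normal(size=15)
    X = np.column_stack([np.ones(15), x])
    fit = pgls_fit(y, X, tree, taxa, lam=1.0)
    ols = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.params, ols.params, atol=1e-10)
    np.testing.assert_allclose(fit.pvalues, ols.pvalues, atol=1e-10)


def test_pgls_recovers_slope_and_lambda():
    """Known slope and lambda on a 64-tip tree, 200 replicates."""
    tree = simulate_tree(64, seed=11)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    V, _ = phylo_covariance(tree, 0.7, taxa)
    chol = np.linalg.cholesky(V + 1e-12 * np.eye(64))
    V0, _ = phylo_covariance(tree, 1.0, taxa)
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 2, 64)
    X = np.column_stack([np.ones(64), x])
    slopes, lams = [], []
    for _ in range(200):
        y = 1.0 + 0.8 * x + 0.4 * (chol @ rng.standard_normal(64))
        fit = pgls_fit(y, X, None, taxa, lam="REML", V0=V0)
        slopes.append(fit.params[1])
        lams.append(fit.lam)
    mc_se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 0.8) < 2 * mc_se
    assert abs(np.mean(lams) - 0.7) < 0.1


def test_pgls_rejects_singular_design():
    tree = simulate_tree(12, seed=2)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    x = np.arange(12.0)
    X = np.column_stack([np.ones(12), x, 2 * x])
    with pytest.raises(ValueError, match="collinear"):
        pgls_fit(x, X, tree, taxa, lam=0.0, names=["intercept", "a", "b"])


# ------------------------------------------------------- allometry test


def test_noiseless_isometric_slope_classified_isometry():
    spec = SimulationSpec(
        n_species=24, bm_sigma=0.0, seed=4, slopes={"TbTh": 1.0}, lifestyle_offsets={}
    )
    tree, df = simulate_comparative_dataset(spec)
    res = allometry_test(df, "TbTh", tree, lam=0.0)
    assert res.classification == "isometry"
    assert res.a_obs == pytest.approx(1.0, abs=1e-10)


def test_noiseless_offset_slope_classified_positive_allometry():
    spec = SimulationSpec(n_species=24, bm_sigma=0.0, seed=4, slopes={"TbTh": 1.5})
    tree, df = simulate_comparative_dataset(spec)
    res = allometry_test(df, "TbTh", tree, lam=0.0)
    assert res.classification == "+allo"
    assert res.a_obs == pytest.approx(1.5, abs=1e-10)


def test_shifted_slope_equals_a_obs_minus_a_iso():
    """Algebraic identity of the baseline-shift device under one covariance."""
    spec = SimulationSpec(n_species=40, bm_sigma=0.25, seed=9)
    tree, df = simulate_comparative_dataset(spec)
    taxa = list(df["species"])
    y = np.log(df["TbSp"].to_numpy())
    x = np.log(df["vl"].to_numpy())
    X = np.column_stack([np.ones_like(x), x])
    fit = pgls_fit(y, X, tree, taxa)
    shifted = pgls_fit(y - 1.0 * x, X, tree, taxa, lam=fit.lam)
    assert shifted.params[1] == pytest.approx(fit.params[1] - 1.0, abs=1e-10)


def test_strong_negative_allometry_detected_with_high_power():
    """TbSp exponent 0.593 against a_iso = 1 rejects in nearly all replicates."""
    rejections = 0
    n_rep = 50
    for rep in range(n_rep):
        spec = SimulationSpec(n_species=69, bm_sigma=0.15, seed=500 + rep)
        tree, df = simulate_comparative_dataset(spec)
        res = allometry_test(df, "TbSp", tree)
        rejections += res.classification == "-allo"
    assert rejections / n_rep > 0.95


# ------------------------------------------------------- BH adjustment


def test_bh_matches_hand_formula_on_ladder():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_p_unchanged_and_ones_stay_one():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)
    out = bh_adjust([0.2, 1.0, 0.01])
    assert out[1] == 1.0


def test_bh_equal_ps_are_fixed_point():
    np.testing.assert_allclose(bh_adjust([0.001] * 6), [0.001] * 6)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
def test_bh_properties(ps):
    """Step-up: never decreases p, stays in [0, 1], preserves ranks."""
    out = bh_adjust(ps)
    assert np.all(out >= np.asarray(ps) - 1e-12)
    assert np.all((out >= 0) & (out <= 1))
    order = np.argsort(ps)
    assert np.all(np.diff(out[order]) >= -1e-12)

    # oracle: direct evaluation of the step-up formula
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    oracle = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * ps[i] / rank)
        oracle[i] = min(running, 1.0)
    np.testing.assert_allclose(out, oracle, atol=1e-12)


# ------------------------------------------------------- lifestyle contrasts


def test_lifestyle_offset_detected_with_high_power():
    """Aerial TbTh +0.4 log units vs fossorial at small residual noise."""
    detected = 0
    n_rep = 60
    for rep in range(n_rep):
        spec = SimulationSpec(
            n_species=69, bm_sigma=0.08, seed=7000 + rep,
            lifestyle_offsets={"TbTh": {"aerial": 0.4}},
        )
        tree, df = simulate_comparative_dataset(spec)
        res = {r.pair: r for r in lifestyle_pairwise(df, "TbTh", tree)}
        detected += res[("fossorial", "aerial")].significant
    assert detected / n_rep > 0.8


def test_pairwise_skips_underpowered_groups():
    spec = SimulationSpec(n_species=20, composition={
        "arboreal": 9, "fossorial": 7, "semifossorial": 2, "aerial": 2}, seed=1)
    tree, df = simulate_comparative_dataset(spec)
    results = lifestyle_pairwise(df, "TbTh", tree)
    skipped = [r for r in results if r.skipped_reason is not None]
    assert skipped and all("3" in r.skipped_reason for r in skipped)
    assert len(results) == 6


def test_pairwise_adjusted_p_never_below_raw():
    spec = SimulationSpec(n_species=40, bm_sigma=0.2, seed=13)
    tree, df = simulate_comparative_dataset(spec)
    for r in lifestyle_pairwise(df, "ConnD", tree):
        if r.skipped_reason is None:
            assert r.p_adjusted >= r.p_raw - 1e-12


# ------------------------------------------------------- size proxy


def test_size_proxy_exact_cube_scaling():
    spec = SimulationSpec(n_species=30, bm_sigma=0.0, seed=21)
    tree, df = simulate_comparative_dataset(spec)
    df = df.assign(mass=2.5 * df["vl"] ** 3)
    res = validate_size_proxy(df, tree, lam=0.0)
    assert res["exponent"] == pytest.approx(3.0, abs=1e-10)
    assert res["p_vs_isometry"] > 0.9


def test_size_proxy_shuffled_mass_has_no_signal():
    spec = SimulationSpec(n_species=40, bm_sigma=0.0, seed=22)
    tree, df = simulate_comparative_dataset(spec)
    rng = np.random.default_rng(0)
    mass = 2.5 * df["vl"] ** 3
    df = df.assign(mass=rng.permutation(mass.to_numpy()))
    res = validate_size_proxy(df, tree, lam=0.0)
    assert res["r_squared"] < 0.2


def test_size_proxy_mild_deviation_usually_non_significant():
    """Exponent 2.95 with noise tuned near r^2 ~ 0.92 at n = 64."""
    non_sig = 0
    n_rep = 40
    rng = np.random.default_rng(31)
    for rep in range(n_rep):
        spec = SimulationSpec(n_species=64, bm_sigma=0.0, seed=800 + rep)
        tree, df = simulate_comparative_dataset(spec)
        logm = math.log(2.5) + 2.95 * np.log(df["vl"]) + rng.normal(0, 0.52, len(df))
        df = df.assign(mass=np.exp(logm))
        res = validate_size_proxy(df, tree)
        non_sig += res["p_vs_isometry"] >= 0.05
    assert non_sig / n_rep > 0.8


def test_size_proxy_requires_ten_masses():
    spec = SimulationSpec(n_species=20, seed=2)
    tree, df = simulate_comparative_dataset(spec)
    df = df.assign(mass=np.where(np.arange(len(df)) < 5, 100.0, np.nan))
    with pytest.raises(ValueError, match="10"):
        validate_size_proxy(df, tree)


# ------------------------------------------------------- bookkeeping


def test_dataset_summary_counts_and_extrema():
    import pandas as pd

    df = pd.DataFrame(
        {
            "species": ["Sciurus vulgaris", "Sciurus niger", "Tamias striatus", "Glis glis"],
            "lifestyle": ["arboreal", "arboreal", "semifossorial", "arboreal"],
            "DA": [0.451, 0.6, 0.883, 0.7],
        }
    )
    s = dataset_summary(df)
    assert s["n_species"] == 4
    assert s["n_genera"] == 3
    assert s["lifestyle_counts"] == {"arboreal": 3, "semifossorial": 1}
    assert s["da_min"] == 0.451 and s["da_max"] == 0.883


def test_species_missing_from_tree_are_named():
    spec = SimulationSpec(n_species=16, seed=3)
    tree, df = simulate_comparative_dataset(spec)
    df.loc[0, "species"] = "Ratufa indica"
    with pytest.raises(ValueError, match="Ratufa indica"):
        allometry_test(df, "TbTh", tree)
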