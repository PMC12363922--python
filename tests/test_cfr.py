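"""Counterfactual engine: Wasserstein estimator, Stage-0 regression,
conditional flows, ITE rule, Shapley attributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import wasserstein_distance

from resprec._autodiff import Tensor
from resprec import cfr
from resprec.cfr import (
    ConditionalFlow,
    ITEEstimate,
    TrainConfig,
    compute_ite,
    fit_naive_plugin,
    fit_stage0,
    fit_stage1_flow,
    fit_stage2_flow,
    head_ite_fn,
    ipm_wasserstein,
    predict_potential,
    recommend_from_ite,
    shap_rationale,
    sqrt_pehe,
)


# ------------------------------------------------------------- Wasserstein

def test_wasserstein_identical_sets_zero():
    x = np.random.default_rng(0).normal(size=50)
    assert ipm_wasserstein(x, x.copy()) == pytest.approx(0.0, abs=1e-12)


def test_wasserstein_point_mass_translation():
    assert ipm_wasserstein(np.array([0.0]), np.array([1.0])) == pytest.approx(1.0)


def test_wasserstein_equal_size_sorted_matching_oracle():
    """1-D equal-size sets: W1 equals the mean absolute difference of the
    sorted samples (100 random pairs, 1e-9 agreement)."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = rng.integers(2, 60)
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n)
        oracle = np.mean(np.abs(np.sort(a) - np.sort(b)))
        assert ipm_wasserstein(a, b) == pytest.approx(oracle, abs=1e-9)


def test_wasserstein_unequal_sizes_match_scipy():
    rng = np.random.default_rng(2)
    a = rng.normal(size=37)
    b = rng.normal(1.0, 1.5, size=61)
    assert ipm_wasserstein(a, b) == pytest.approx(
        wasserstein_distance(a, b), abs=1e-9
    )


def test_wasserstein_symmetry_and_multivariate_assignment():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(20, 3))
    b = rng.normal(0.5, 1, size=(20, 3))
    d_ab = ipm_wasserstein(a, b)
    assert d_ab == pytest.approx(ipm_wasserstein(b, a), abs=1e-9)
    assert d_ab > 0
    assert ipm_wasserstein(a, a + 2.0) == pytest.approx(
        2.0 * np.sqrt(3), rel=1e-6
    )


def test_wasserstein_empty_set_rejected():
    with pytest.raises(ValueError):
        ipm_wasserstein(np.array([]), np.array([1.0]))


# ------------------------------------------------------- ITE rule plumbing

@pytest.mark.parametrize("pn,ph,expected", [(0.4, 0.3, 0.1), (0.5, 0.5, 0.0),
                                            (0.0, 1.0, -1.0)])
def test_compute_ite(pn, ph, expected):
    assert compute_ite(pn, ph) == pytest.approx(expected)


def test_compute_ite_rejects_out_of_range():
    with pytest.raises(ValueError):
        compute_ite(1.2, 0.5)


@pytest.mark.parametrize("ite,expected", [
    (-0.05, "NIV_preferred"), (0.0005, "Indifferent"), (0.001, "Indifferent"),
    (-0.001, "Indifferent"), (0.0011, "HFNC_preferred"), (1.0, "HFNC_preferred"),
    (-1.0, "NIV_preferred"), (0.0, "Indifferent"),
])
def test_recommendation_thresholds(ite, expected):
    assert recommend_from_ite(ite) == expected


@given(st.floats(-1.0, 1.0, allow_nan=False))
@settings(max_examples=300, deadline=None)
def test_recommendation_is_a_partition(ite):
    label = recommend_from_ite(ite)
    assert label in {"NIV_preferred", "HFNC_preferred", "Indifferent"}
    # the three bands are exclusive and exhaustive
    assert (label == "NIV_preferred") == (ite < -0.001)
    assert (label == "HFNC_preferred") == (ite > 0.001)


def test_ite_estimate_consistency():
    est = ITEEstimate.from_probs(0.42, 0.3, n_samples=100)
    assert est.ite == pytest.approx(0.12)
    assert est.recommendation == "HFNC_preferred"


# ----------------------------------------------------------------- Stage 0

def _toy_linear_data(n=400, d=12, seed=0, effect=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    t = (rng.random(n) < 0.5).astype(int)
    logit = 0.8 * X[:, 0] - 0.6 * X[:, 1] + effect * t
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return X, t, y


def test_stage0_single_arm_rejected():
    X, t, y = _toy_linear_data()
    with pytest.raises(ValueError, match="both treatment arms"):
        fit_stage0(X, np.ones_like(t), y, TrainConfig())


def test_stage0_high_accuracy_on_separable_data():
    """Nearly separable toy problem: factual training accuracy >= 0.95."""
    rng = np.random.default_rng(5)
    n = 200
    X = rng.normal(size=(n, 4))
    t = (rng.random(n) < 0.5).astype(int)
    y = (X[:, 0] + 0.05 * rng.normal(size=n) > 0).astype(int)
    cfg = TrainConfig(seed=0, l1_scale=0.05, val_fraction=0.0, alpha=0.0)
    model = fit_stage0(X, t, y, cfg)
    pn, ph = model.head_probs(X)
    pred = np.where(t == 1, pn, ph) > 0.5
    assert (pred == y).mean() >= 0.95


def test_alpha_zero_equals_independent_regressions():
    """With balancing and arm-coupling off, Stage 0 must reduce exactly to
    the two per-arm plug-in fits."""
    X, t, y = _toy_linear_data(seed=7)
    cfg = TrainConfig(seed=3, alpha=0.0, fuse_ratio=0.0)
    m = fit_stage0(X, t, y, cfg)
    naive = fit_naive_plugin(X, t, y, cfg)
    pn_a, ph_a = m.head_probs(X)
    pn_b, ph_b = naive(X)
    assert np.allclose(pn_a, pn_b) and np.allclose(ph_a, ph_b)


def test_stage0_deterministic_given_seed():
    X, t, y = _toy_linear_data(seed=9)
    cfg = TrainConfig(seed=1)
    m1 = fit_stage0(X, t, y, cfg)
    m2 = fit_stage0(X, t, y, cfg)
    assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.b, m2.b)


def test_increasing_alpha_does_not_increase_representation_ipm():
    """Median over 3 seeds: the final between-arm IPM of the representation
    is non-increasing from alpha=0 to a large alpha."""
    gaps = []
    for seed in (0, 1, 2):
        X, t, y = _toy_linear_data(n=500, seed=seed)
        # induce imbalance: treatment depends on X0
        rng = np.random.default_rng(seed + 100)
        t = (rng.random(500) < 1 / (1 + np.exp(-1.5 * X[:, 0]))).astype(int)
        logit = 0.8 * X[:, 0] - 0.6 * X[:, 1] + 0.5 * t
        y = (rng.random(500) < 1 / (1 + np.exp(-logit))).astype(int)
        ipms = []
        for alpha in (0.0, 5.0):
            m = fit_stage0(X, t, y, TrainConfig(seed=seed, alpha=alpha))
            rep = m.represent(X)
            ipms.append(ipm_wasserstein(rep[t == 1][:150], rep[t == 0][:150]))
        gaps.append(ipms[1] - ipms[0])
    assert np.median(gaps) <= 1e-9


def test_head_probs_within_unit_interval():
    X, t, y = _toy_linear_data(seed=11)
    m = fit_stage0(X, t, y, TrainConfig(seed=0))
    pn, ph = m.head_probs(X)
    assert np.all((pn > 0) & (pn < 1)) and np.all((ph > 0) & (ph < 1))


# ------------------------------------------------------------------- flows

@pytest.fixture(scope="module")
def gaussian_flow():
    """Stage-1 flow fit on a continuous 1-D surrogate outcome whose
    conditional law is Gaussian with treatment-dependent location/scale."""
    rng = np.random.default_rng(21)
    n = 5000
    rep = rng.normal(size=(n, 2))
    t = (rng.random(n) < 0.5).astype(int)
    y = np.where(t == 1, 1.0 + 0.5 * rng.normal(size=n),
                 -1.0 + 1.5 * rng.normal(size=n))
    cfg = TrainConfig(seed=2)
    flow = fit_stage1_flow(rep * 0.0, t, y, cfg, dequantize=False)
    return flow, t, y


def test_flow_density_integrates_to_one(gaussian_flow):
    flow, _, _ = gaussian_flow
    grid = np.linspace(-12, 12, 4001)
    for arm in (0.0, 1.0):
        ctx = np.tile([0.0, 0.0, arm], (grid.size, 1))
        dens = np.exp(flow.log_density(grid, ctx))
        integral = np.trapezoid(dens, grid)
        assert integral == pytest.approx(1.0, abs=0.01)


def test_flow_matches_conditional_moments(gaussian_flow):
    """Flow mean/variance per treatment within 10% (scale) of the truth."""
    flow, _, _ = gaussian_flow
    rng = np.random.default_rng(3)
    z = rng.normal(size=20000)
    for arm, (mu, sd) in ((1.0, (1.0, 0.5)), (0.0, (-1.0, 1.5))):
        ctx = np.tile([0.0, 0.0, arm], (z.size, 1))
        samples = flow.inverse(z, ctx).ravel()
        assert abs(samples.mean() - mu) < 0.1 * max(1.0, abs(mu)) + 0.1 * sd
        assert abs(samples.std() - sd) < 0.15 * sd


def test_flow_roundtrip_inverse_of_forward():
    """|inverse(forward(y)) - y| < 1e-4 on 1000 random points."""
    rng = np.random.default_rng(4)
    flow = ConditionalFlow(3, TrainConfig(seed=0), rng)
    y = rng.normal(size=(1000, 1)) * 2
    ctx = rng.normal(size=(1000, 3))
    z, _ = flow.forward(Tensor(y), Tensor(ctx))
    back = flow.inverse(z.value, ctx)
    assert np.max(np.abs(back - y)) < 1e-4


def test_stage2_flow_normalizes_latents():
    rng = np.random.default_rng(6)
    n = 4000
    t = (rng.random(n) < 0.5).astype(int)
    latents = np.where(t == 1, 0.8 + 1.3 * rng.normal(size=n),
                       -0.5 + 0.7 * rng.normal(size=n))
    flow = fit_stage2_flow(latents, t, TrainConfig(seed=0))
    z, _ = flow.forward(
        Tensor(latents.reshape(-1, 1)), Tensor(t.reshape(-1, 1).astype(float))
    )
    # mapped latents should be close to the standard base in both arms
    for arm in (0, 1):
        sub = z.value.ravel()[t == arm]
        assert abs(sub.mean()) < 0.15
        assert abs(sub.std() - 1.0) < 0.15


# ------------------------------------------------------- bundle prediction

@pytest.fixture(scope="module")
def small_bundle():
    X, t, y = _toy_linear_data(n=600, seed=15, effect=0.8)
    cfg = TrainConfig(seed=0, flow_epochs=30)
    bundle = cfr.fit_bundle(X, t, y, cfg, feature_names=[f"f{i}" for i in range(X.shape[1])])
    return bundle, X


def test_predict_potential_reproducible_and_bounded(small_bundle):
    bundle, X = small_bundle
    p1 = predict_potential(bundle, X[:50], mc_samples=100, seed=3)
    p2 = predict_potential(bundle, X[:50], mc_samples=100, seed=3)
    assert np.array_equal(p1[0], p2[0]) and np.array_equal(p1[1], p2[1])
    for p in p1:
        assert np.all((p >= 0) & (p <= 1))
    p3 = predict_potential(bundle, X[:50], mc_samples=100, seed=4)
    assert not np.array_equal(p1[0], p3[0])


def test_predict_potential_rejects_zero_samples(small_bundle):
    bundle, X = small_bundle
    with pytest.raises(ValueError):
        predict_potential(bundle, X[:2], mc_samples=0)


def test_bundle_serialization_roundtrip(tmp_path, small_bundle):
    bundle, X = small_bundle
    path = tmp_path / "bundle.json"
    cfr.save_bundle(bundle, str(path))
    loaded = cfr.load_bundle(str(path))
    p_orig = predict_potential(bundle, X[:20], mc_samples=50, seed=1)
    p_load = predict_potential(loaded, X[:20], mc_samples=50, seed=1)
    assert np.allclose(p_orig[0], p_load[0]) and np.allclose(p_orig[1], p_load[1])
    assert loaded.feature_names == bundle.feature_names


# ----------------------------------------------------------------- Shapley

def test_shap_constant_model_gives_zero_attributions():
    fn = lambda X: np.zeros(np.atleast_2d(X).shape[0])
    out = shap_rationale(fn, np.ones(6), np.zeros(6),
                         [f"f{i}" for i in range(6)], k=6)
    assert all(abs(a) < 1e-12 for _, a in out)


def test_shap_additive_model_exact():
    """For ite = 0.2*x1 the Shapley value of x1 is exactly
    0.2*(x1 - background_x1) and all other attributions vanish."""
    fn = lambda X: 0.2 * np.atleast_2d(X)[:, 1]
    x = np.array([0.5, 3.0, -1.0, 2.0])
    bg = np.array([0.0, 1.0, 0.0, 0.0])
    out = shap_rationale(fn, x, bg, ["a", "b", "c", "d"], k=4,
                         n_permutations=8, seed=0)
    assert out[0][0] == "b"
    assert out[0][1] == pytest.approx(0.2 * (3.0 - 1.0), abs=1e-12)
    assert all(abs(a) < 1e-12 for name, a in out[1:])


def test_shap_attributions_sum_to_ite_gap():
    rng = np.random.default_rng(8)
    w = rng.normal(size=5)
    fn = lambda X: np.tanh(np.atleast_2d(X) @ w)
    x, bg = rng.normal(size=5), np.zeros(5)
    out = shap_rationale(fn, x, bg, [f"f{i}" for i in range(5)], k=5,
                         n_permutations=64, seed=0)
    total = sum(a for _, a in out)
    assert total == pytest.approx(float(fn(x)[0] - fn(bg)[0]), abs=1e-10)


def test_shap_top_ranking_stable_across_seeds():
    X, t, y = _toy_linear_data(n=500, d=8, seed=19)
    m = fit_stage0(X, t, y, TrainConfig(seed=0))
    fn = head_ite_fn(m)
    x, bg = X[0], X.mean(axis=0)
    names = [f"f{i}" for i in range(8)]
    tops = []
    for seed in (0, 1, 2):
        out = shap_rationale(fn, x, bg, names, k=5, n_permutations=128, seed=seed)
        tops.append([n for n, _ in out[:3]])
    assert tops[0] == tops[1] == tops[2]


def test_shap_k_bounds():
    fn = lambda X: np.atleast_2d(X)[:, 0]
    with pytest.raises(ValueError):
        shap_rationale(fn, np.ones(3), np.zeros(3), ["a", "b", "c"], k=0)
    out = shap_rationale(fn, np.ones(3), np.zeros(3), ["a", "b", "c"], k=50)
    assert len(out) == 3


def test_sqrt_pehe_zero_for_perfect_estimate():
    ite = np.array([0.1, -0.2, 0.0])
    assert sqrt_pehe(ite, ite) == 0.0
    assert sqrt_pehe(ite + 0.1, ite) == pytest.approx(0.1)
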