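import numpy as np
import pytest

from etmpheno import (
    CohortTable,
    KernelSpec,
    TissueRecord,
    decode_value,
    encode_labels,
    gp_loocv,
    kernel_eval,
    rmse_table,
)
from etmpheno.gp import KERNELS


# ----------------------------------------------------------------- kernels

@pytest.mark.parametrize("name", KERNELS)
def test_kernel_at_zero_distance_is_signal_variance(name):
    spec = KernelSpec(name, sigma2=2.5, length_scale=0.7)
    x = np.array([0.3, -1.2, 4.0])
    assert kernel_eval(spec, x, x) == pytest.approx(2.5)
    noisy = KernelSpec(name, sigma2=2.5, length_scale=0.7, noise2=0.1)
    assert kernel_eval(noisy, x, x) == pytest.approx(2.6)


def test_squared_exponential_at_one_length_scale():
    spec = KernelSpec("squared_exponential", sigma2=1.0, length_scale=2.0)
    assert kernel_eval(spec, [0.0], [2.0]) == pytest.approx(np.exp(-0.5))


def test_rational_quadratic_limits_to_squared_exponential():
    se = KernelSpec("squared_exponential", sigma2=1.3, length_scale=0.9)
    rq = KernelSpec("rational_quadratic", sigma2=1.3, length_scale=0.9, rq_alpha=1e6)
    for r in (0.2, 0.9, 2.0):
        k_se = kernel_eval(se, [0.0], [r])
        k_rq = kernel_eval(rq, [0.0], [r])
        assert k_rq == pytest.approx(k_se, rel=1e-4)


def test_kernel_dimension_mismatch():
    spec = KernelSpec("matern52")
    with pytest.raises(ValueError, match="dimension"):
        kernel_eval(spec, [1.0, 2.0], [1.0])


def test_kernel_eval_matches_sklearn():
    """Dual route: closed-form kernels against scikit-learn's implementations."""
    from sklearn.gaussian_process.kernels import RBF, Matern, RationalQuadratic

    rng = np.random.default_rng(3)
    pairs = rng.standard_normal((5, 2, 3))
    mapping = {
        "squared_exponential": RBF(0.8),
        "exponential": Matern(0.8, nu=0.5),
        "matern52": Matern(0.8, nu=2.5),
        "rational_quadratic": RationalQuadratic(0.8, 1.7),
    }
    for name, sk in mapping.items():
        spec = KernelSpec(name, sigma2=1.0, length_scale=0.8, rq_alpha=1.7)
        for x, y in pairs:
            expected = sk(x.reshape(1, -1), y.reshape(1, -1))[0, 0]
            assert kernel_eval(spec, x, y) == pytest.approx(expected, rel=1e-10)


# ----------------------------------------------------------------- labels

def test_label_encoding_alphabetical():
    np.testing.assert_array_equal(encode_labels(["AN", "CA", "FA"]), [1.0, 2.0, 3.0])


def test_label_decoding_nearest_integer():
    assert decode_value(1.4) == "AN"
    assert decode_value(1.6) == "CA"
    assert decode_value(2.7) == "FA"
    assert decode_value(1.5) == "AN"   # exact ties round down
    assert decode_value(-3.0) == "AN"  # clipped
    assert decode_value(9.0) == "FA"


def test_encode_decode_identity_on_exact_codes():
    for g in ("AN", "CA", "FA"):
        assert decode_value(float(encode_labels([g])[0])) == g


def test_unknown_label_rejected():
    with pytest.raises(ValueError, match="unknown group"):
        encode_labels(["AN", "XX"])


# ----------------------------------------------------------------- GP basics

def test_gp_posterior_interpolates_with_vanishing_noise():
    """With the noise variance pinned near zero, the posterior mean passes
    through the training targets at the training inputs (5-point toy)."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, WhiteKernel

    x = np.linspace(0, 1, 5).reshape(-1, 1)
    y = np.array([0.0, 0.8, 0.3, -0.5, 1.0])
    gp = GaussianProcessRegressor(
        kernel=RBF(0.3) + WhiteKernel(1e-12, "fixed"), optimizer=None
    )
    gp.fit(x, y)
    np.testing.assert_allclose(gp.predict(x), y, atol=1e-6)


def _cluster_cohort(jitter=0.003, n=6, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    centers = {"AN": 0.02, "CA": 0.2, "FA": 0.8}
    for g, c in centers.items():
        for i in range(n):
            v = c * (1 + jitter * rng.standard_normal())
            recs.append(TissueRecord(f"{g}{i}", g, 1000.0, 0.3, v, 30.0))
    return CohortTable(recs)


@pytest.mark.parametrize("kernel", KERNELS)
def test_separated_clusters_are_easy(kernel):
    cohort = _cluster_cohort()
    rep = gp_loocv(cohort, ("k",), kernel, seed=0)
    assert rep.rmse < 0.1
    assert rep.n_failed_folds == 0


def test_shuffled_labels_never_beat_true_labels(fixture_cohort):
    """Permuting group labels destroys the feature-label relation, so LOOCV
    RMSE must not improve for any kernel."""
    rng = np.random.default_rng(4)
    recs = list(fixture_cohort.records)
    groups = [r.group for r in recs]
    shuffled_groups = list(groups)
    rng.shuffle(shuffled_groups)
    shuffled = CohortTable(
        [
            TissueRecord(r.subject_id, g, r.Z_15k, r.K, r.k_stiff, r.pctR)
            for r, g in zip(recs, shuffled_groups)
        ]
    )
    subset = ("Z", "K", "k", "%R")
    for kernel in KERNELS:
        true_rmse = gp_loocv(fixture_cohort, subset, kernel, seed=0).rmse
        perm_rmse = gp_loocv(shuffled, subset, kernel, seed=0).rmse
        assert perm_rmse >= true_rmse, kernel


def test_loocv_invariant_to_sample_order(fixture_cohort):
    fwd = gp_loocv(fixture_cohort, ("K", "k"), "matern52", seed=0)
    rev_cohort = CohortTable(list(fixture_cohort.records)[::-1])
    rev = gp_loocv(rev_cohort, ("K", "k"), "matern52", seed=0)
    a = fwd.per_sample["prediction"].to_numpy()
    b = rev.per_sample["prediction"].to_numpy()[::-1]
    # same training sets per fold; tiny float jitter from row permutation only
    np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-6)
    assert fwd.rmse == pytest.approx(rev.rmse, rel=1e-5)


def test_gp_preconditions(fixture_cohort):
    with pytest.raises(ValueError):
        gp_loocv(fixture_cohort, (), "matern52")
    with pytest.raises(KeyError):
        gp_loocv(fixture_cohort, ("bogus",), "matern52")
    with pytest.raises(ValueError):
        gp_loocv(fixture_cohort, ("Z",), "not_a_kernel")


def test_rmse_table_covers_all_kernel_subset_pairs():
    ms_truth = _cluster_cohort(jitter=0.05, n=3, seed=1)
    tab = rmse_table(ms_truth, seed=0, n_restarts=0)
    assert tab.shape == (4, 15)
    assert (tab.to_numpy() >= 0).all()
    assert list(tab.index) == list(KERNELS)
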