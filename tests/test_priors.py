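import numpy as np
import pytest

from precmap import (
    BoldSeries,
    CohortParams,
    build_template,
    concat_reduce,
    dual_regression,
    estimate_template,
    match_components,
    noise_sd_for_snr,
    simulate_subject,
    spatial_ica,
)
from precmap.priors import TemplatePrior, split_half_noise_map


# -- PCA reduction -----------------------------------------------------------

def test_concat_reduce_lossless_at_full_dim(rng):
    Y = rng.standard_normal((30, 100))
    reduced, shares = concat_reduce([BoldSeries(Y)], 30)
    # spatial covariance preserved up to rotation
    Yc = Y - Y.mean(axis=0)
    np.testing.assert_allclose(reduced.T @ reduced, Yc.T @ Yc, atol=1e-8)
    assert shares.sum() == pytest.approx(1.0, abs=1e-10)


def test_concat_reduce_rank3_data(rng):
    C = rng.standard_normal((80, 3))
    S = rng.standard_normal((3, 200))
    reduced, shares = concat_reduce([BoldSeries(C @ S)], 3)
    assert shares.sum() > 0.999


def test_concat_reduce_matches_eigen_oracle(rng):
    C = rng.standard_normal((60, 3))
    S = rng.standard_normal((3, 150))
    Y = C @ S
    _, shares = concat_reduce([BoldSeries(Y)], 2)
    Yc = Y - Y.mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(Yc @ Yc.T))[::-1]
    np.testing.assert_allclose(
        shares, evals[:2] / evals.sum(), atol=1e-10
    )


def test_concat_reduce_rejects_bad_dim(rng):
    with pytest.raises(ValueError):
        concat_reduce([BoldSeries(rng.standard_normal((10, 20)))], 11)


# -- spatial ICA -------------------------------------------------------------

def test_ica_recovers_bimodal_sources(rng):
    # two independent bimodal (two-Gaussian-mixture) sources on 500 vertices
    s1 = rng.choice([-2.0, 2.0], 500) + 0.3 * rng.standard_normal(500)
    s2 = rng.choice([-2.0, 2.0], 500) + 0.3 * rng.standard_normal(500)
    S = np.vstack([s1, s2])
    A = np.array([[1.0, 0.4], [0.3, 1.0], [0.7, -0.5]])
    X = A @ S
    dec = spatial_ica(X, 2, seed=0)
    corr = np.abs(np.corrcoef(dec.group_maps, S)[:2, 2:])
    # each source recovered by some component, up to permutation
    assert corr.max(axis=0).min() > 0.99


def test_ica_separated_input_is_permutation(rng):
    S = np.vstack([
        rng.choice([-1.0, 3.0], 400),
        rng.choice([-3.0, 1.0], 400),
    ])
    dec = spatial_ica(S, 2, seed=0)
    corr = np.abs(np.corrcoef(dec.group_maps, S)[:2, 2:])
    perm_like = (corr > 0.95).astype(int)
    assert perm_like.sum() == 2
    assert (perm_like.sum(axis=0) == 1).all()


def test_ica_flags_nonconvergence_on_gaussian_sources(rng):
    X = rng.standard_normal((4, 800))
    with pytest.warns(Warning):
        dec = spatial_ica(X, 3, seed=0, max_iter=3, tol=1e-12)
    assert not dec.converged


def test_ica_components_unit_variance_positive_skew(rng):
    s1 = rng.gamma(1.0, 1.0, 600)
    s2 = rng.choice([-2.0, 2.0], 600)
    X = rng.standard_normal((3, 2)) @ np.vstack([s1, s2])
    dec = spatial_ica(X, 2, seed=1)
    np.testing.assert_allclose(dec.group_maps.std(axis=1), 1.0, atol=1e-8)
    from scipy.stats import skew
    assert (skew(dec.group_maps, axis=1) >= -1e-8).all()


# -- dual regression ---------------------------------------------------------

def test_dual_regression_exact_model_recovery(rng):
    # orthogonal spatial rows, data = C Sᵀ exactly
    S = np.zeros((3, 90))
    S[0, :30] = rng.standard_normal(30)
    S[1, 30:60] = rng.standard_normal(30)
    S[2, 60:] = rng.standard_normal(30)
    C = rng.standard_normal((40, 3))
    tc, maps = dual_regression(BoldSeries(C @ S), S)
    for l in range(3):
        assert abs(np.corrcoef(maps[l], S[l])[0, 1]) > 0.999999


def test_dual_regression_zero_data(rng):
    S = rng.standard_normal((2, 50))
    tc, maps = dual_regression(np.zeros((20, 50)), S)
    np.testing.assert_allclose(tc, 0.0, atol=1e-12)
    np.testing.assert_allclose(maps, 0.0, atol=1e-12)


def test_dual_regression_matches_pinv_oracle(rng):
    S = rng.standard_normal((3, 60))
    Y = rng.standard_normal((25, 60))
    tc, maps = dual_regression(Y, S)
    tc_oracle = Y @ np.linalg.pinv(S)
    np.testing.assert_allclose(tc, tc_oracle, atol=1e-10)
    tc_norm = tc_oracle / tc_oracle.std(axis=0, ddof=0)
    maps_oracle = np.linalg.pinv(tc_norm) @ Y
    np.testing.assert_allclose(maps, maps_oracle, atol=1e-10)


def test_dual_regression_rank_deficient_maps(rng):
    row = rng.standard_normal(40)
    with pytest.raises(ValueError, match="collinear"):
        dual_regression(rng.standard_normal((10, 40)), np.vstack([row, row]))


# -- template estimation -----------------------------------------------------

def test_identical_maps_zero_variance(rng):
    m = rng.standard_normal((2, 30))
    mu, var = estimate_template([m] * 5, correct_noise=False)
    np.testing.assert_allclose(mu, m, atol=1e-12)
    np.testing.assert_allclose(var, 0.0, atol=1e-12)


def test_two_subject_variance_closed_form():
    a = np.full((1, 4), 1.0)
    b = np.full((1, 4), 3.0)
    _, var = estimate_template([a, b], correct_noise=False)
    np.testing.assert_allclose(var, (1.0 - 3.0) ** 2 / 2.0)


def test_noise_correction_floors_at_zero(rng):
    maps = [rng.standard_normal((2, 40)) for _ in range(6)]
    noise = [np.full((2, 40), 10.0) for _ in range(6)]  # huge noise estimate
    _, var_corr = estimate_template(maps, correct_noise=True,
                                    noise_var_maps=noise)
    _, var_raw = estimate_template(maps, correct_noise=False)
    assert (var_corr <= var_raw + 1e-12).all()
    assert (var_corr >= 0).all()
    np.testing.assert_array_equal(var_corr, 0.0)


def test_single_subject_rejected(rng):
    with pytest.raises(ValueError):
        estimate_template([rng.standard_normal((2, 10))])


def test_match_components_greedy_assignment(rng):
    ref = rng.standard_normal((3, 80))
    perm_true = np.array([2, 0, 1])
    signs_true = np.array([1.0, -1.0, 1.0])
    comps = np.empty_like(ref)
    for i, (j, s) in enumerate(zip(perm_true, signs_true)):
        comps[j] = s * ref[i] + 0.01 * rng.standard_normal(80)
    perm, signs = match_components(comps, ref)
    np.testing.assert_array_equal(perm, perm_true)
    np.testing.assert_array_equal(signs, signs_true)
    aligned = signs[:, None] * comps[perm]
    for i in range(3):
        assert np.corrcoef(aligned[i], ref[i])[0, 1] > 0.99


# -- template recovery from a simulated reference sample ---------------------

def test_template_recovery_36_subjects(template_mid):
    """Mean and between-subject variance of the empirical prior are
    recovered from 36 dual-regressed reference subjects at SNR 1."""
    tmpl = template_mid
    nu = noise_sd_for_snr(tmpl, 1.0)
    params = CohortParams(age_slope=0.0, preterm_offset=0.0, noise_sd=nu)
    rng = np.random.default_rng(42)
    series = [
        simulate_subject(tmpl, float(rng.uniform(37, 45)), False, params,
                         n_frames=300, seed=500 + i, n_spikes=0,
                         session_id=f"ref{i}")[0]
        for i in range(36)
    ]
    est = build_template(series, tmpl.mean, tmpl.network_names,
                         correct_noise=True)
    for l in range(tmpl.n_networks):
        assert np.corrcoef(est.mean[l], tmpl.mean[l])[0, 1] > 0.95
    rel_err = np.abs(est.between_var - tmpl.between_var) / tmpl.between_var
    assert np.median(rel_err) < 0.30


def test_split_half_noise_map_scales_with_noise(template_small):
    # at low noise the estimator floors at the finite-sample dual-regression
    # error (signal-dependent), so compare well-separated noise levels
    params_low = CohortParams(age_slope=0.0, preterm_offset=0.0, noise_sd=0.1)
    params_high = CohortParams(age_slope=0.0, preterm_offset=0.0, noise_sd=1.0)
    s_low, _ = simulate_subject(template_small, 40.0, False, params_low,
                                n_frames=200, seed=0, n_spikes=0)
    s_high, _ = simulate_subject(template_small, 40.0, False, params_high,
                                 n_frames=200, seed=0, n_spikes=0)
    n_low = split_half_noise_map(s_low, template_small.mean).mean()
    n_high = split_half_noise_map(s_high, template_small.mean).mean()
    assert n_high > 2 * n_low


def test_template_prior_validates_shapes():
    with pytest.raises(ValueError):
        TemplatePrior(["a"], np.zeros((2, 5)), np.zeros((2, 5)))
    with pytest.raises(ValueError):
        TemplatePrior(["a", "b"], np.zeros((2, 5)), -np.ones((2, 5)))
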