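import numpy as np
import pytest

from precmap import (
    BoldSeries,
    CohortParams,
    compute_tstat,
    dual_regression,
    fit_template_ica,
    noise_sd_for_snr,
    simulate_subject,
    threshold_masks,
)
from precmap.priors import TemplatePrior


def _random_instance(rng, V=30, L=2, T=50, nu2=0.7):
    mu = rng.standard_normal((L, V))
    sig2 = rng.uniform(0.2, 1.0, (L, V))
    A = rng.standard_normal((T, L))
    s = mu + np.sqrt(sig2) * rng.standard_normal((L, V))
    Y = A @ s + np.sqrt(nu2) * rng.standard_normal((T, V))
    return TemplatePrior([f"n{i}" for i in range(L)], mu, sig2), A, Y, s


# -- E-step against the conjugate closed form --------------------------------

def test_posterior_matches_conjugate_oracle(rng):
    """With A and ν² frozen at truth the posterior is the closed-form
    Bayesian linear-model posterior (30 vertices, 2 networks, 50 frames)."""
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, mixing_init=A,
                            noise_var_init=0.7, update_mixing=False,
                            update_noise=False)
    for v in range(30):
        P = np.diag(1.0 / tmpl.between_var[:, v]) + A.T @ A / 0.7
        C = np.linalg.inv(P)
        m = C @ (np.diag(1.0 / tmpl.between_var[:, v]) @ tmpl.mean[:, v]
                 + A.T @ Y[:, v] / 0.7)
        np.testing.assert_allclose(post.post_mean[:, v], m, atol=1e-10)
        np.testing.assert_allclose(post.post_sd[:, v], np.sqrt(np.diag(C)),
                                   atol=1e-10)


def test_zero_prior_variance_returns_prior_mean(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    point = TemplatePrior(tmpl.network_names, tmpl.mean,
                          np.zeros_like(tmpl.between_var))
    post = fit_template_ica(BoldSeries(Y), point, mixing_init=A,
                            noise_var_init=0.7, update_mixing=False,
                            update_noise=False)
    np.testing.assert_allclose(post.post_mean, point.mean, atol=1e-8)
    assert not post.tested.any()
    assert np.isnan(compute_tstat(post)).all()


# -- EM sanity ---------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_loglik_monotone_and_posterior_shrinks(seed):
    rng = np.random.default_rng(seed)
    tmpl, A, Y, _ = _random_instance(rng, V=40, L=3, T=60)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=40, seed=0)
    ll = post.loglik_trace
    assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))
    assert (post.post_sd <= np.sqrt(tmpl.between_var) + 1e-12).all()


def test_posterior_sd_decreases_with_more_frames(rng):
    tmpl, A, Y, _ = _random_instance(rng, V=20, L=2, T=200, nu2=1.0)
    post_short = fit_template_ica(BoldSeries(Y[:50]), tmpl,
                                  mixing_init=A[:50], noise_var_init=1.0,
                                  update_mixing=False, update_noise=False)
    post_long = fit_template_ica(BoldSeries(Y), tmpl, mixing_init=A,
                                 noise_var_init=1.0, update_mixing=False,
                                 update_noise=False)
    assert (post_long.post_sd < post_short.post_sd + 1e-12).all()


def test_consistency_high_snr(template_mid):
    """Nearly noiseless data → posterior mean approaches the true maps."""
    nu = 1e-3
    params = CohortParams(noise_sd=nu)
    series, truth = simulate_subject(template_mid, 40.0, False, params,
                                     n_frames=400, seed=1, n_spikes=0)
    post = fit_template_ica(series, template_mid, seed=0)
    c = np.corrcoef(post.post_mean.ravel(),
                    truth["subject_maps"].ravel())[0, 1]
    assert c > 0.99


def test_permutation_equivariance(rng):
    """Permuting network order permutes all outputs: exactly for plain EM,
    and up to the (order-dependent) coordinate-ascent residual for the
    norm-constrained mixing update."""
    tmpl, A, Y, _ = _random_instance(rng, V=25, L=3, T=60)
    perm = np.array([2, 0, 1])
    tmpl_p = TemplatePrior([tmpl.network_names[i] for i in perm],
                           tmpl.mean[perm], tmpl.between_var[perm])
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=20, seed=0,
                            constrain_mixing=False)
    post_p = fit_template_ica(BoldSeries(Y), tmpl_p, max_iter=20, seed=0,
                              constrain_mixing=False)
    np.testing.assert_allclose(post_p.post_mean, post.post_mean[perm],
                               atol=1e-8)
    np.testing.assert_allclose(post_p.post_sd, post.post_sd[perm], atol=1e-8)
    np.testing.assert_allclose(post_p.mixing, post.mixing[:, perm], atol=1e-8)
    post_c = fit_template_ica(BoldSeries(Y), tmpl, max_iter=20, seed=0)
    post_cp = fit_template_ica(BoldSeries(Y), tmpl_p, max_iter=20, seed=0)
    np.testing.assert_allclose(post_cp.post_mean, post_c.post_mean[perm],
                               atol=1e-3)


def test_shrinkage_beats_dual_regression(template_mid):
    """Template-ICA posterior means are closer to the true subject maps than
    plain dual-regression estimates (the method's raison d'être)."""
    nu = noise_sd_for_snr(template_mid, 1.0)
    params = CohortParams(noise_sd=nu)
    wins = 0
    for seed in range(5):
        series, truth = simulate_subject(template_mid, 40.0, False, params,
                                         n_frames=400, seed=seed, n_spikes=0)
        post = fit_template_ica(series, template_mid, max_iter=50, seed=0)
        _, dr = dual_regression(series, template_mid.mean)
        t = truth["subject_maps"]
        wins += (np.sqrt(((post.post_mean - t) ** 2).mean())
                 < np.sqrt(((dr - t) ** 2).mean()))
    assert wins >= 4


def test_too_few_frames_rejected(rng):
    tmpl, A, Y, _ = _random_instance(rng, V=10, L=4, T=50)
    with pytest.raises(ValueError):
        fit_template_ica(BoldSeries(Y[:3]), tmpl)


# -- t-statistics ------------------------------------------------------------

def test_tstat_elementwise_division(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=5, seed=0)
    t = compute_tstat(post)
    np.testing.assert_allclose(t, post.post_mean / post.post_sd, atol=1e-12)


def test_tstat_simple_values(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=2, seed=0)
    post.post_mean = np.zeros_like(post.post_mean)
    assert np.nanmax(np.abs(compute_tstat(post))) == 0.0
    post.post_mean = 2.0 * post.post_sd
    np.testing.assert_allclose(compute_tstat(post), 2.0, atol=1e-12)


# -- masks -------------------------------------------------------------------

def test_full_mask_when_signal_overwhelms(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=2, seed=0)
    post.post_mean = np.abs(post.post_mean) + 100.0 * post.post_sd
    mask = threshold_masks(post, alpha=0.05, gamma=0.0,
                           correction="bonferroni")
    assert mask.mask.all()


def test_bonferroni_mask_subset_of_uncorrected(rng):
    tmpl, A, Y, _ = _random_instance(rng, V=60)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=5, seed=0)
    m_bonf = threshold_masks(post, correction="bonferroni").mask
    m_none = threshold_masks(post, correction="none").mask
    m_bh = threshold_masks(post, correction="bh_fdr").mask
    assert (m_bonf <= m_none).all()
    assert (m_bh <= m_none).all()


def test_per_network_gamma_vector(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=2, seed=0)
    lo = threshold_masks(post, gamma=np.array([0.0, 100.0]), correction="none")
    assert not lo.mask[1].any()  # unreachable threshold for network 2


def test_mask_parameter_validation(rng):
    tmpl, A, Y, _ = _random_instance(rng)
    post = fit_template_ica(BoldSeries(Y), tmpl, max_iter=2, seed=0)
    with pytest.raises(ValueError):
        threshold_masks(post, alpha=1.5)
    with pytest.raises(ValueError):
        threshold_masks(post, gamma=-0.1)
    with pytest.raises(ValueError):
        threshold_masks(post, correction="holm-sidak-banana")
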