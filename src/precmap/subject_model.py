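"""Subject-level Bayesian estimation of resting-state network maps.

The hierarchical (template-ICA) model treats the empirical prior — a
population mean map μ and between-subject variance σ² per network and vertex
— as a Gaussian prior on each subject's true network maps:

    y_v = A s_v + e_v,   s_v ~ N(μ_v, diag(σ²_v)),   e_v ~ N(0, ν² I_T)

with y_v the (normalised, censored) T-frame time course at vertex v, A the
T×L mixing matrix shared across vertices, and ν² an isotropic noise variance.
A and ν² are estimated by expectation–maximisation; the E-step posterior of
s_v is Gaussian with closed-form mean and covariance, so the output of the
fit is a posterior mean map, a posterior SD map, and their ratio — the
subject's "t-statistic" map (a posterior z-score under the conjugate
Gaussian model) — from which binary engagement masks are derived by
null-hypothesis testing.

The empirical-Bayes shrinkage toward μ is what makes short neonatal scans
usable: vertices with little data information are pulled toward the
population template, while strongly informative data overrides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import BoldSeries
from .priors import TemplatePrior, dual_regression

_SD_FLOOR = 1e-12  # reported posterior SD at point-mass (σ² = 0) vertices


@dataclass
class SubjectPosterior:
    """Posterior summaries of one session's network maps."""

    post_mean: np.ndarray        # L × V
    post_sd: np.ndarray          # L × V, > 0 (floor at point-mass vertices)
    mixing: np.ndarray           # T × L
    noise_var: float
    tested: np.ndarray           # L × V bool: False where the prior is a point mass
    n_iter: int
    loglik_trace: np.ndarray
    network_names: list = field(default_factory=list)
    session_id: str = ""

    @property
    def t_map(self) -> np.ndarray:
        return compute_tstat(self)


@dataclass
class NetworkMask:
    """Binary engagement masks from one-sided tests of s_v > gamma."""

    mask: np.ndarray             # L × V bool
    alpha: float
    gamma: float
    correction: str
    p_values: np.ndarray | None = None


def _estep(AtA, AtY, ssq_resid, mu, sig2, nu2):
    """Batched Gaussian posterior over vertices.

    Uses the symmetric factorisation C_v = D^{1/2} (I + D^{1/2} AᵀA D^{1/2}/ν²)⁻¹
    D^{1/2} with D = diag(σ²_v), which remains valid (and yields the point
    mass) where σ² = 0.

    Returns posterior mean (L×V), covariance stack (V×L×L) and the total
    marginal log-likelihood.
    """
    L, V = mu.shape
    S = np.sqrt(sig2.T)                         # V × L
    M = np.eye(L)[None] + (S[:, :, None] * S[:, None, :]) * (AtA / nu2)[None]
    cho = np.linalg.cholesky(M)                 # V × L × L
    # residual projections R = Aᵀ(y − Aμ)/ν², shape L×V
    R = (AtY - AtA @ mu) / nu2
    Minv_U = np.linalg.solve(M, (S * R.T)[:, :, None])[:, :, 0]
    # posterior covariance C = D^{1/2} M⁻¹ D^{1/2}
    Minv = np.linalg.solve(M, np.broadcast_to(np.eye(L), (V, L, L)).copy())
    C = S[:, :, None] * Minv * S[:, None, :]
    m = mu + np.einsum("vab,bv->av", C, R)
    # marginal log-likelihood via the determinant lemma / Woodbury:
    # logdet(ν²I_T + A D Aᵀ) = T log ν² + logdet M
    logdet_M = 2.0 * np.sum(np.log(np.diagonal(cho, axis1=1, axis2=2)), axis=1)
    quad = ssq_resid / nu2 - np.einsum("vl,vl->v", S * R.T, Minv_U)
    return m, C, logdet_M, quad


def _update_mixing_unit_norm(A, YmT, Ess, T_frames, n_passes: int = 3):
    """Constrained M-step for the mixing matrix: maximise the expected
    complete-data log-likelihood subject to each column having unit temporal
    variance (‖a_l‖² = T).

    Column-wise coordinate ascent: holding the other columns fixed, the
    optimal direction for column l is YmT[:, l] − Σ_{k≠l} a_k Ess[k, l],
    rescaled to the constraint norm.  Each update does not decrease the
    expected log-likelihood, so the overall EM iteration stays monotone.
    """
    A = A.copy()
    L = A.shape[1]
    target = np.sqrt(T_frames)
    for _ in range(n_passes):
        for l in range(L):
            r = YmT[:, l] - A @ Ess[:, l] + A[:, l] * Ess[l, l]
            nrm = np.linalg.norm(r)
            if nrm > 0:
                A[:, l] = target * r / nrm
    return A


def _loglik(T_frames, V, nu2, logdet_M, quad):
    return float(
        -0.5 * V * T_frames * np.log(2.0 * np.pi * nu2)
        - 0.5 * np.sum(logdet_M)
        - 0.5 * np.sum(quad)
    )


def fit_template_ica(
    series: BoldSeries,
    template: TemplatePrior,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    mixing_init: np.ndarray | None = None,
    noise_var_init: float | None = None,
    update_mixing: bool = True,
    update_noise: bool = True,
    constrain_mixing: bool = True,
) -> SubjectPosterior:
    """Fit the template-ICA model to one session by EM.

    The mixing matrix is initialised from dual regression of the data against
    the prior mean maps (or taken from ``mixing_init``); the E-step computes
    the per-vertex Gaussian posterior of the subject maps, the M-step updates
    A and ν² in closed form.  Iteration stops when the relative change of the
    observed-data log-likelihood falls below ``tol``.  The log-likelihood
    trace is non-decreasing up to numerical tolerance (EM guarantee).

    With ``constrain_mixing`` (default) each mixing column is constrained to
    unit temporal variance in the M-step (column-wise constrained ascent, a
    generalised-EM step that keeps the likelihood monotone).  This removes
    the amplitude degeneracy between the time courses and the maps — without
    it the scale of the subject maps is pinned only softly by the prior and
    drifts between sessions, making amplitudes incomparable across a cohort.

    Setting ``update_mixing=False`` / ``update_noise=False`` freezes A / ν²
    (useful for validating the E-step against the conjugate closed form).
    """
    Y = series.data
    T_frames, V = Y.shape
    mu = template.mean
    sig2 = template.between_var
    L = mu.shape[0]
    if V != mu.shape[1]:
        raise ValueError("series and template vertex counts differ")
    if T_frames < L:
        raise ValueError("fewer frames than networks")

    if mixing_init is not None:
        A = np.asarray(mixing_init, dtype=float).copy()
    else:
        C0, _ = dual_regression(series, mu)
        sd = C0.std(axis=0, ddof=0)
        A = C0 / np.maximum(sd, 1e-300)
    if update_mixing and constrain_mixing:
        # start on the constraint manifold so every GEM step is an ascent
        A = np.sqrt(T_frames) * A / np.linalg.norm(A, axis=0, keepdims=True)
    if noise_var_init is not None:
        nu2 = float(noise_var_init)
    else:
        resid = Y - A @ np.linalg.lstsq(A, Y, rcond=None)[0]
        nu2 = max(float(np.mean(resid**2)), 1e-12)

    loglik_trace = []
    n_iter = 0
    for it in range(max_iter):
        AtA = A.T @ A
        AtY = A.T @ Y
        Amu = A @ mu
        ssq_resid = np.sum((Y - Amu) ** 2, axis=0)
        m, C, logdet_M, quad = _estep(AtA, AtY, ssq_resid, mu, sig2, nu2)
        ll = _loglik(T_frames, V, nu2, logdet_M, quad)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        loglik_trace.append(ll)
        n_iter = it + 1
        if it > 0 and abs(ll - loglik_trace[-2]) <= tol * abs(loglik_trace[-2]):
            break
        if not (update_mixing or update_noise):
            break
        # M-step. Second moments: E[s sᵀ] summed over vertices.
        Ess = C.sum(axis=0) + m @ m.T                    # L × L
        if update_mixing:
            YmT = Y @ m.T                                # T × L
            if constrain_mixing:
                A = _update_mixing_unit_norm(A, YmT, Ess, T_frames)
            else:
                A = np.linalg.solve(Ess.T, YmT.T).T
        if update_noise:
            AtA_new = A.T @ A
            resid_ss = (
                np.sum(Y**2)
                - 2.0 * np.sum((A.T @ Y) * m)
                + np.sum(AtA_new * Ess)
            )
            nu2 = max(float(resid_ss / (T_frames * V)), 1e-12)

    # final E-step at the converged parameters
    AtA = A.T @ A
    AtY = A.T @ Y
    ssq_resid = np.sum((Y - A @ mu) ** 2, axis=0)
    m, C, logdet_M, quad = _estep(AtA, AtY, ssq_resid, mu, sig2, nu2)
    loglik_trace.append(_loglik(T_frames, V, nu2, logdet_M, quad))

    post_var = np.maximum(np.diagonal(C, axis1=1, axis2=2).T, 0.0)  # L × V
    tested = sig2 > 0
    post_sd = np.sqrt(post_var)
    post_sd[~tested] = _SD_FLOOR
    m = np.where(tested, m, mu)  # exact point mass at σ² = 0

    return SubjectPosterior(
        post_mean=m,
        post_sd=post_sd,
        mixing=A,
        noise_var=nu2,
        tested=tested,
        n_iter=n_iter,
        loglik_trace=np.asarray(loglik_trace),
        network_names=list(template.network_names),
        session_id=series.session_id,
    )


def compute_tstat(posterior: SubjectPosterior) -> np.ndarray:
    """Elementwise posterior mean / posterior SD; NaN at point-mass vertices
    (excluded from testing)."""
    sd = posterior.post_sd
    if np.any((sd <= 0) & posterior.tested):
        raise ValueError("zero posterior SD at a tested vertex")
    t = posterior.post_mean / sd
    t = np.where(posterior.tested, t, np.nan)
    return t


def threshold_masks(
    posterior: SubjectPosterior,
    alpha: float = 0.05,
    gamma: float = 0.0,
    correction: str = "bonferroni",
) -> NetworkMask:
    """One-sided engagement test H0: s_v ≤ gamma per vertex and network.

    The statistic (post_mean − gamma)/post_sd is referred to the standard
    normal; multiple-comparison correction is applied across the tested
    vertices within each network ('bonferroni' default, 'bh_fdr' or 'none').
    ``gamma`` may be a scalar or a length-L vector of per-network engagement
    thresholds in map units.  Point-mass vertices are never tested and never
    enter the mask.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    gamma_arr = np.asarray(gamma, dtype=float)
    if np.any(gamma_arr < 0):
        raise ValueError("gamma must be nonnegative")
    methods = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh", "none": None}
    if correction not in methods:
        raise ValueError(
            f"unknown correction {correction!r}; use one of {sorted(methods)}"
        )
    L, V = posterior.post_mean.shape
    if gamma_arr.ndim == 1:
        gamma_arr = gamma_arr[:, None]  # per-network thresholds
    z = (posterior.post_mean - gamma_arr) / posterior.post_sd
    pvals = stats.norm.sf(z)
    mask = np.zeros((L, V), dtype=bool)
    for l in range(L):
        idx = posterior.tested[l]
        if not idx.any():
            continue
        p = pvals[l, idx]
        if methods[correction] is None:
            rej = p <= alpha
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rej = multipletests(p, alpha=alpha, method=methods[correction])[0]
        mask[l, idx] = rej
    pv = np.where(posterior.tested, pvals, np.nan)
    return NetworkMask(mask=mask, alpha=alpha, gamma=gamma,
                       correction=correction, p_values=pv)
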