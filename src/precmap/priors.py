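"""Empirical priors for template ICA: group ICA, dual regression, and
vertex-wise mean / between-subject variance of the resting-state networks.

The template (empirical prior) is built from a held-out reference sample:
group ICA on temporally concatenated, PCA-reduced data identifies the network
spatial components; dual regression then yields a rough per-subject map of
each network; the vertex-wise sample mean and (optionally noise-corrected)
between-subject variance of those maps form the prior handed to the
subject-level Bayesian model.  Reference sessions are recorded on the prior
and must never re-enter downstream cohort analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import BoldSeries


@dataclass
class TemplatePrior:
    """Per-network, per-vertex prior mean and between-subject variance."""

    network_names: list
    mean: np.ndarray          # L × V
    between_var: np.ndarray   # L × V, nonnegative
    reference_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.between_var = np.asarray(self.between_var, dtype=float)
        if self.mean.shape != self.between_var.shape:
            raise ValueError("mean and between_var shapes differ")
        if len(self.network_names) != self.mean.shape[0]:
            raise ValueError("network_names length does not match map count")
        if np.any(self.between_var < 0):
            raise ValueError("between-subject variance must be nonnegative")

    @property
    def n_networks(self) -> int:
        return self.mean.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.mean.shape[1]


@dataclass
class GroupDecomposition:
    """Group-ICA spatial components (unit spatial variance, positive skew)."""

    group_maps: np.ndarray       # L × V
    explained_var: np.ndarray    # per-component share of reduced-data variance
    reduction_dim: int
    converged: bool = True


def concat_reduce(series_list: list, target_dim: int):
    """Temporally concatenate sessions and reduce the time dimension by PCA.

    Returns a ``target_dim × V`` matrix whose rows are the top temporal
    principal components scaled by their singular values (so the spatial
    covariance of the data is preserved up to the retained rank), plus the
    per-component explained-variance shares.
    """
    mats = []
    for s in series_list:
        X = s.data if isinstance(s, BoldSeries) else np.asarray(s, dtype=float)
        mats.append(X - X.mean(axis=0, keepdims=True))
    Y = np.concatenate(mats, axis=0)
    if target_dim > Y.shape[0]:
        raise ValueError("target_dim exceeds total frame count")
    if target_dim < 1:
        raise ValueError("target_dim must be positive")
    # economy SVD over time; rows of diag(s) @ Vt carry the spatial structure
    U, sv, Vt = np.linalg.svd(Y, full_matrices=False)
    reduced = sv[:target_dim, None] * Vt[:target_dim]
    total = np.sum(sv**2)
    shares = sv[:target_dim] ** 2 / total if total > 0 else np.zeros(target_dim)
    return reduced, shares


def spatial_ica(
    reduced: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GroupDecomposition:
    """Spatial ICA of the reduced data by fixed-point negentropy maximisation.

    Vertices are treated as samples and reduced temporal components as mixed
    channels.  Components are sign-fixed to positive skewness and ordered by
    the share of reduced-data variance they explain.  Non-convergence raises a
    warning and returns the best iterate with ``converged=False``.
    """
    reduced = np.asarray(reduced, dtype=float)
    d, V = reduced.shape
    if n_components > d:
        raise ValueError("more components than reduced dimensions")
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(reduced.T)  # V × L, unit variance
    if any(issubclass(w.category, (ConvergenceWarning, UserWarning))
           for w in caught):
        converged = False
        warnings.warn(
            "spatial ICA did not converge; returning best iterate",
            ConvergenceWarning,
            stacklevel=2,
        )
    maps = sources.T.copy()
    # unit spatial variance + positive-skew sign convention
    maps /= np.maximum(maps.std(axis=1, ddof=0, keepdims=True), 1e-300)
    signs = np.where(stats.skew(maps, axis=1) >= 0, 1.0, -1.0)
    maps *= signs[:, None]
    # explained variance of each component in the reduced data
    energy = np.sum(ica.mixing_**2, axis=0) * np.sum(sources**2, axis=0)
    order = np.argsort(energy)[::-1]
    maps = maps[order]
    shares = energy[order] / max(np.sum(reduced**2), 1e-300)
    return GroupDecomposition(
        group_maps=maps,
        explained_var=shares,
        reduction_dim=d,
        converged=converged,
    )


def dual_regression(series, group_maps: np.ndarray):
    """Two-stage least squares from group spatial maps to subject maps.

    Stage 1 regresses every frame on the group maps (across vertices) to get
    subject time courses; stage 2 regresses every vertex's time course on the
    variance-normalised stage-1 time courses to get subject spatial maps.

    Returns ``(timecourses T×L, subject_maps L×V)``.
    """
    Y = series.data if isinstance(series, BoldSeries) else np.asarray(series, float)
    S = np.asarray(group_maps, dtype=float)
    L = S.shape[0]
    if np.linalg.matrix_rank(S) < L:
        # identify (near-)collinear components for the error message
        corr = np.corrcoef(S)
        bad = [
            (i, j)
            for i in range(L)
            for j in range(i + 1, L)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"group maps are rank deficient; collinear pairs: {bad}")
    C, *_ = np.linalg.lstsq(S.T, Y.T, rcond=None)  # L × T
    C = C.T                                        # T × L
    sd = C.std(axis=0, ddof=0)
    Cn = C / np.maximum(sd, 1e-300)
    M, *_ = np.linalg.lstsq(Cn, Y, rcond=None)     # L × V
    return C, M


def estimate_template(
    subject_maps: list,
    correct_noise: bool = True,
    noise_var_maps: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-wise mean and between-subject variance over subject maps.

    ``noise_var_maps`` are per-subject estimates of the within-subject sampling
    variance of each map entry (from split-half dual regression); when
    ``correct_noise`` is set their average is subtracted from the raw unbiased
    sample variance and the result floored at zero.
    """
    if len(subject_maps) < 2:
        raise ValueError("template estimation needs at least two subjects")
    stack = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    mu = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    if correct_noise and noise_var_maps is not None:
        noise = np.stack([np.asarray(m, dtype=float) for m in noise_var_maps])
        var = np.maximum(var - noise.mean(axis=0), 0.0)
    return mu, var


def split_half_noise_map(series, group_maps: np.ndarray) -> np.ndarray:
    """Within-subject sampling-variance estimate of the dual-regression map.

    Dual regression is run on the two temporal halves; if each half-map equals
    the true map plus independent noise of variance 2τ² (twice that of the
    full-series map), then (m₁ − m₂)²/4 is an unbiased estimate of τ².
    """
    Y = series.data if isinstance(series, BoldSeries) else np.asarray(series, float)
    half = Y.shape[0] // 2
    _, m1 = dual_regression(Y[:half], group_maps)
    _, m2 = dual_regression(Y[half:], group_maps)
    return (m1 - m2) ** 2 / 4.0


def match_components(
    group_maps: np.ndarray, reference_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy assignment of ICA components to reference networks by maximal
    absolute spatial correlation (ties broken by component order).

    Returns ``(perm, signs)`` such that ``signs[:, None] * group_maps[perm]``
    is aligned with ``reference_maps`` row for row.
    """
    G = np.asarray(group_maps, dtype=float)
    R = np.asarray(reference_maps, dtype=float)
    Gz = (G - G.mean(axis=1, keepdims=True))
    Rz = (R - R.mean(axis=1, keepdims=True))
    Gz /= np.maximum(np.linalg.norm(Gz, axis=1, keepdims=True), 1e-300)
    Rz /= np.maximum(np.linalg.norm(Rz, axis=1, keepdims=True), 1e-300)
    corr = Rz @ Gz.T  # ref × comp
    L = R.shape[0]
    perm = np.full(L, -1, dtype=int)
    signs = np.ones(L)
    used = np.zeros(G.shape[0], dtype=bool)
    abs_corr = np.abs(corr)
    for _ in range(L):
        masked = abs_corr.copy()
        masked[perm >= 0, :] = -np.inf
        masked[:, used] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        used[j] = True
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
    return perm, signs


def build_template(
    series_list: list,
    group_maps: np.ndarray,
    network_names: list,
    reference_ids: list | None = None,
    correct_noise: bool = True,
) -> TemplatePrior:
    """Dual-regress every reference session against the group maps and reduce
    to the empirical prior (mean, between-subject variance)."""
    maps, noise_maps = [], []
    ids = list(reference_ids) if reference_ids is not None else []
    for s in series_list:
        _, m = dual_regression(s, group_maps)
        maps.append(m)
        if correct_noise:
            noise_maps.append(split_half_noise_map(s, group_maps))
        if reference_ids is None and isinstance(s, BoldSeries):
            ids.append(s.session_id)
    mu, var = estimate_template(
        maps, correct_noise=correct_noise,
        noise_var_maps=noise_maps if correct_noise else None,
    )
    return TemplatePrior(
        network_names=list(network_names), mean=mu, between_var=var,
        reference_ids=ids,
    )
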