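"""Synthetic neonatal cohorts with known resting-state network structure.

Everything downstream of raw data — censoring, priors, the Bayesian subject
model, network metrics, cohort statistics — is validated against cohorts
generated here, where the ground truth (subject maps, mixing time courses,
planted motion spikes, age and prematurity effects) is known exactly.

Generative model
----------------
* L smooth nonnegative network "bump" templates with unit peak live on a
  sphere mesh, with a smooth positive between-subject variance field σ².
* A subject scanned at postmenstrual age ``a`` with preterm status ``b`` has
  per-network gain ``g_l = 1 + slope_l·(a − 40) + offset_l·b`` and a true map
  drawn vertex-wise from Normal(g_l·μ_l, σ²_l).
* BOLD is mixing-matrix × maps + white Gaussian noise: the T×L mixing matrix
  has temporally smooth, orthogonalised, unit-variance columns.
* Head motion is planted as transient global signal shifts: at each spike
  frame the whole frame is displaced by a fixed amplitude (alternating sign),
  so a DVARS censoring pass flags every planted frame (and its successor).

Defaults mirror the study conditions the pipeline is meant for: 2300 frames
at TR = 392 ms, eight networks, birth/scan age ranges of a preterm + term
neonatal cohort, preterm defined as birth before 37 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .mesh import SurfaceMesh, farthest_point_sample
from .preprocess import BoldSeries, DEFAULT_TR_SECONDS, smooth_geodesic
from .priors import TemplatePrior

PRETERM_CUTOFF_WEEKS = 37.0

#: Eight networks modelled in the neonatal cohort, primary to higher-order.
DEFAULT_NETWORK_NAMES = [
    "lateral_motor", "medial_motor", "somatosensory", "auditory",
    "primary_visual", "motor_association", "visual_association",
    "default_mode",
]

#: Birth/scan age ranges (weeks) per group, matching the cohort design:
#: "preterm" = born and scanned before 37 weeks PMA, "term" = born at/after 37.
DEFAULT_AGE_RANGES = {
    "term_birth": (37.1, 42.3),
    "term_scan": (37.4, 44.9),
    "preterm_birth": (25.6, 36.9),
    "preterm_scan": (29.3, 44.9),
    "preterm_first_scan": (29.3, 36.9),
    "term_equivalent_scan": (37.0, 44.9),
}


@dataclass
class CohortParams:
    """True cohort-level effects injected by the generator.

    age_slope and preterm_offset act multiplicatively on the template mean
    (per-network gain), in fraction-per-week and fraction units respectively;
    interaction is the prematurity × age modulation (zero in the study
    conditions); noise_sd ν is the BOLD white-noise SD; spike_amplitude is the
    global level-shift size, and spike_rate the per-frame spike probability.
    """

    age_slope: float | np.ndarray = 0.05
    preterm_offset: float | np.ndarray = -0.3
    interaction: float | np.ndarray = 0.0
    noise_sd: float = 1.0
    spike_amplitude: float | None = None   # default: 20 × noise_sd
    spike_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.spike_amplitude is None:
            self.spike_amplitude = 10.0 * self.noise_sd if self.noise_sd > 0 else 10.0


@dataclass
class GroundTruth:
    """Per-session generative truth, keyed by session_id."""

    subject_maps: dict = field(default_factory=dict)    # L × V true maps
    mixing_courses: dict = field(default_factory=dict)  # T × L
    spike_frames: dict = field(default_factory=dict)    # sorted int arrays
    gains: dict = field(default_factory=dict)           # length-L gain vectors
    cohort_params: CohortParams | None = None
    template: TemplatePrior | None = None


def network_gain(
    scan_age: float, preterm: bool, params: CohortParams, n_networks: int,
    age_center: float = 40.0,
) -> np.ndarray:
    """Per-network amplitude gain g = 1 + slope·(age − 40) + offset·preterm
    (+ interaction·preterm·(age − 40))."""
    slope = np.broadcast_to(np.asarray(params.age_slope, float), (n_networks,))
    offset = np.broadcast_to(np.asarray(params.preterm_offset, float), (n_networks,))
    inter = np.broadcast_to(np.asarray(params.interaction, float), (n_networks,))
    d = scan_age - age_center
    return 1.0 + slope * d + (offset + inter * d) * float(preterm)


def make_templates(
    mesh: SurfaceMesh,
    n_networks: int = 8,
    smoothness_mm: float = 10.0,
    var_scale: float = 0.05,
    seed: int = 0,
    network_names: list | None = None,
) -> TemplatePrior:
    """Smooth unit-peak network bumps with a smooth positive variance field.

    Network peaks are placed by farthest-point sampling so they are mutually
    separated by well over 2× the bump half-width.  Each mean map is a
    flat-top geodesic bump exp(−ln2·(d/smoothness)⁸) — a parcel-like plateau
    with unit peak, half maximum at d = smoothness_mm and a steep border.
    The between-subject variance is ``var_scale`` times a smooth positive
    field concentrated where the network is present (small background floor),
    modulated by a smooth random field.
    """
    L, V = n_networks, mesh.n_vertices
    if L < 2:
        raise ValueError("need at least two networks")
    if L > V:
        raise ValueError("more networks than vertices")
    if var_scale < 0:
        raise ValueError("var_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    peaks = farthest_point_sample(mesh, L, seed=seed)
    dist = mesh.geodesic_distances(peaks)  # L × V
    # flat-top (super-Gaussian) bump: plateau near the peak with a steep
    # border at d ≈ smoothness_mm (half-maximum), like a cortical parcel
    mean = np.exp(-np.log(2.0) * (dist / smoothness_mm) ** 8)
    if var_scale == 0:
        var = np.zeros((L, V))
    else:
        # between-subject variability concentrates where the network is
        # present (plus a small background floor), modulated by a smooth
        # random field — mirroring cortical RSN variance topography
        rough = rng.standard_normal((L, V))
        smooth = smooth_geodesic(rough, mesh, fwhm_mm=2.0 * smoothness_mm)
        sd = np.maximum(smooth.std(axis=1, keepdims=True), 1e-300)
        jitter = 1.0 + 0.5 * np.tanh(smooth / sd)
        var = var_scale * (0.1 + mean) * jitter
    names = list(network_names) if network_names is not None else [
        DEFAULT_NETWORK_NAMES[i] if i < len(DEFAULT_NETWORK_NAMES) else f"net{i:02d}"
        for i in range(L)
    ]
    return TemplatePrior(network_names=names[:L], mean=mean, between_var=var)


def _smooth_timecourses(T: int, L: int, rng, smooth_frames: float = 4.0) -> np.ndarray:
    """Temporally smooth, column-centered, orthogonalised unit-variance T×L
    mixing matrix.  Orthogonalisation keeps the EM problem well conditioned
    at short scan lengths."""
    C = gaussian_filter1d(rng.standard_normal((T, L)), smooth_frames, axis=0)
    C -= C.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(C)
    Q *= np.sign(np.diag(R))  # deterministic sign convention
    return Q * np.sqrt(T)


def _spike_offsets(T: int, spike_frames: np.ndarray, amplitude: float,
                   rng) -> np.ndarray:
    """Global per-frame offset trace: a transient whole-brain shift of the
    stated amplitude at each spike frame (alternating sign), as from a brief
    head movement.  DVARS flags the spike frame and its successor; a spike
    surviving inside a retained block corrupts only that single frame."""
    offsets = np.zeros(T)
    sign = float(rng.choice([-1.0, 1.0]))
    for t in np.sort(spike_frames):
        offsets[t] = amplitude * sign
        sign = -sign
    return offsets


def simulate_subject(
    template: TemplatePrior,
    scan_age: float,
    preterm: bool,
    params: CohortParams,
    n_frames: int = 2300,
    seed: int = 0,
    session_id: str = "sub-000_ses-1",
    n_spikes: int | None = None,
    tr_seconds: float = DEFAULT_TR_SECONDS,
):
    """Simulate one session: draw the true subject maps from the template,
    mix them with smooth time courses, add white noise and motion spikes.

    Returns ``(BoldSeries, truth)`` where ``truth`` is a dict holding the
    true maps, mixing matrix, spike frames and gains.
    """
    L, V = template.mean.shape
    if n_frames < 2 * L:
        raise ValueError("n_frames must be at least 2 × n_networks")
    if params.noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    g = network_gain(scan_age, preterm, params, L)
    maps = g[:, None] * template.mean + (
        np.sqrt(template.between_var) * rng.standard_normal((L, V))
    )
    C = _smooth_timecourses(n_frames, L, rng)
    Y = C @ maps
    if params.noise_sd > 0:
        Y = Y + params.noise_sd * rng.standard_normal((n_frames, V))
    if n_spikes is None:
        n_spikes = int(rng.binomial(n_frames - 1, params.spike_rate))
    if n_spikes > 0:
        # never plant at frame 0: the first DVARS entry is undefined
        spikes = rng.choice(np.arange(1, n_frames), size=n_spikes, replace=False)
        spikes = np.sort(spikes)
        Y = Y + _spike_offsets(n_frames, spikes, params.spike_amplitude, rng)[:, None]
    else:
        spikes = np.array([], dtype=int)
    series = BoldSeries(Y, tr_seconds=tr_seconds, session_id=session_id)
    truth = {
        "subject_maps": maps,
        "mixing_courses": C,
        "spike_frames": spikes,
        "gain": g,
    }
    return series, truth


def noise_sd_for_snr(template: TemplatePrior, snr: float) -> float:
    """Noise SD giving the requested signal-to-noise ratio, where signal
    power is the vertex-average of Σ_l μ_l² (unit-variance mixing columns)."""
    signal_var = float(np.mean(np.sum(template.mean**2, axis=0)))
    return float(np.sqrt(signal_var / snr))


def simulate_cohort(
    template: TemplatePrior,
    n_term: int,
    n_preterm: int,
    n_longitudinal_pairs: int = 0,
    age_ranges: dict | None = None,
    params: CohortParams | None = None,
    n_frames: int = 2300,
    seed: int = 0,
):
    """Simulate a full cohort of sessions with known age/prematurity effects.

    Groups follow the study design: ``n_term`` term-born singletons scanned
    near term, ``n_preterm`` preterm-born singletons scanned anywhere from the
    preterm period to term-equivalent age, and ``n_longitudinal_pairs``
    preterm infants each scanned twice (preterm age, then term-equivalent
    age) sharing a subject_id.

    Returns ``(series_list, cohort_table, ground_truth)``.  The cohort table
    has one row per session with scan_age ≥ birth_age, preterm ⇔ birth_age
    < 37 weeks, and a motion column left NaN until censoring fills it.
    """
    if n_term + n_preterm + n_longitudinal_pairs <= 0:
        raise ValueError("cohort is empty")
    if min(n_term, n_preterm, n_longitudinal_pairs) < 0:
        raise ValueError("group sizes must be nonnegative")
    ranges = dict(DEFAULT_AGE_RANGES)
    if age_ranges:
        ranges.update(age_ranges)
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(seed)
    sessions, rows = [], []
    truth = GroundTruth(cohort_params=params, template=template)

    def _add(subject_id, ses, birth, scan, sex):
        sid = f"{subject_id}_ses-{ses}"
        series, t = simulate_subject(
            template, scan, birth < PRETERM_CUTOFF_WEEKS, params,
            n_frames=n_frames, seed=int(rng.integers(2**31)), session_id=sid,
        )
        sessions.append(series)
        truth.subject_maps[sid] = t["subject_maps"]
        truth.mixing_courses[sid] = t["mixing_courses"]
        truth.spike_frames[sid] = t["spike_frames"]
        truth.gains[sid] = t["gain"]
        rows.append({
            "session_id": sid, "subject_id": subject_id,
            "scan_age": scan, "birth_age": birth, "sex": sex,
            "preterm": bool(birth < PRETERM_CUTOFF_WEEKS), "motion": np.nan,
        })

    counter = 0
    for _ in range(n_term):
        birth = rng.uniform(*ranges["term_birth"])
        lo, hi = ranges["term_scan"]
        scan = rng.uniform(max(lo, birth), hi)
        _add(f"sub-{counter:04d}", 1, birth, scan, rng.choice(["F", "M"]))
        counter += 1
    for _ in range(n_preterm):
        birth = rng.uniform(*ranges["preterm_birth"])
        lo, hi = ranges["preterm_scan"]
        scan = rng.uniform(max(lo, birth + 0.1), hi)
        _add(f"sub-{counter:04d}", 1, birth, scan, rng.choice(["F", "M"]))
        counter += 1
    for _ in range(n_longitudinal_pairs):
        birth = rng.uniform(*ranges["preterm_birth"])
        lo1, hi1 = ranges["preterm_first_scan"]
        scan1 = rng.uniform(max(lo1, birth + 0.1), hi1)
        scan2 = rng.uniform(*ranges["term_equivalent_scan"])
        sex = rng.choice(["F", "M"])
        sub = f"sub-{counter:04d}"
        _add(sub, 1, birth, scan1, sex)
        _add(sub, 2, birth, scan2, sex)
        counter += 1

    table = pd.DataFrame(rows)
    return sessions, table, truth
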