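"""Session-level network summary metrics.

Connectivity strength for a network is the surface-area-weighted mean of the
t-statistic map within the subject's binary engagement mask; the
winner-takes-all parcellation assigns every vertex to the network with the
largest map value; Dice overlap quantifies longitudinal topographic
stability of a network's mask between two sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .subject_model import NetworkMask, SubjectPosterior, compute_tstat

#: overlap_labels codes
OVERLAP_NEITHER, OVERLAP_FIRST, OVERLAP_SECOND, OVERLAP_BOTH = 0, 1, 2, 3


def connectivity_strength(t_map: np.ndarray, mask: np.ndarray,
                          mesh: SurfaceMesh) -> float:
    """Area-weighted mean t within the mask: Σ aᵥtᵥ / Σ aᵥ over masked v.

    An empty mask yields NaN (flagged missing) — never zero, which would bias
    trajectory slopes.
    """
    t_map = np.asarray(t_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if t_map.shape != (mesh.n_vertices,) or mask.shape != t_map.shape:
        raise ValueError("map/mask do not match mesh vertex count")
    if not mask.any():
        return float("nan")
    a = mesh.vertex_area[mask]
    return float(np.sum(a * t_map[mask]) / np.sum(a))


def wta_parcellation(
    t_maps: np.ndarray,
    require_significant: bool = False,
    masks: np.ndarray | None = None,
) -> np.ndarray:
    """Winner-takes-all labels in [0, L]: 1-based index of the network with
    the highest value per vertex; exact ties go to the lowest index.

    With ``require_significant``, vertices belonging to no engagement mask are
    left unassigned (label 0).
    """
    t_maps = np.asarray(t_maps, dtype=float)
    if t_maps.ndim != 2 or t_maps.shape[0] < 2:
        raise ValueError("need an L×V stack with L >= 2")
    vals = np.where(np.isfinite(t_maps), t_maps, -np.inf)
    labels = np.argmax(vals, axis=0) + 1  # argmax takes lowest index on ties
    if require_significant:
        if masks is None:
            raise ValueError("masks are required when require_significant is set")
        labels = np.where(np.asarray(masks, bool).any(axis=0), labels, 0)
    return labels.astype(np.int32)


def mask_overlap(mask_a: np.ndarray, mask_b: np.ndarray,
                 mesh: SurfaceMesh) -> tuple[float, np.ndarray]:
    """Area-weighted Dice overlap of two masks plus a per-vertex label map
    (0 neither, 1 first only, 2 second only, 3 both)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != (mesh.n_vertices,) or b.shape != a.shape:
        raise ValueError("masks do not match mesh vertex count")
    labels = np.zeros(mesh.n_vertices, dtype=np.int32)
    labels[a & ~b] = OVERLAP_FIRST
    labels[b & ~a] = OVERLAP_SECOND
    labels[a & b] = OVERLAP_BOTH
    area = mesh.vertex_area
    denom = area[a].sum() + area[b].sum()
    if denom == 0:
        return float("nan"), labels
    dice = 2.0 * area[a & b].sum() / denom
    return float(dice), labels


def session_records(
    posterior: SubjectPosterior,
    mask: NetworkMask,
    mesh: SurfaceMesh,
    covariates: dict,
) -> pd.DataFrame:
    """One tidy row per network for a session: strength, mask area, covariates.

    ``covariates`` must carry scan_age, birth_age, sex, preterm and motion
    (and may carry subject_id); empty-mask networks get NaN strength.
    """
    rows = []
    t = compute_tstat(posterior)
    for l, name in enumerate(posterior.network_names):
        m = mask.mask[l]
        rows.append({
            "session_id": posterior.session_id,
            "network": name,
            "strength": connectivity_strength(t[l], m, mesh),
            "mask_area": float(mesh.vertex_area[m].sum()),
            **covariates,
        })
    return pd.DataFrame(rows)
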