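"""Procrustes superimposition and articulation derotation.

Implements ordinary (pairwise) and generalized Procrustes analysis for
2D landmark configurations, plus the "angle-fixing" preprocessing that
removes the balance movement of an articulated subset (the horse's neck)
by rigidly rotating it about a shared vertex so that a three-point angle
is identical across specimens.

Conventions
-----------
* Partial Procrustes by default: every configuration is translated to
  the origin and scaled to unit centroid size; rotation is then the only
  fitted parameter.  Full-Procrustes residual scaling is available via
  ``scaling="full"``.
* Reflections are never part of the fitted transform — all photographs
  are normalized to one facing direction before digitizing, so an
  improper fit would be an artefact.
* In 2D the optimal rotation has a closed form: for centered shapes
  A, B the angle is atan2(Σ(x_A·y_B − y_A·x_B), Σ(x_A·x_B + y_A·y_B)),
  which lets the generalized fit run fully vectorized over specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConvergenceWarning, DegenerateConfigurationError
from .io_formats import LandmarkConfiguration, PointScheme, configs_to_array

__all__ = [
    "AlignedEnsemble", "PairAlignment", "centroid_size", "align_pair",
    "gpa", "procrustes_distance", "measure_angle", "derotate",
    "derotate_sample", "normalize_shape",
]


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared distances from the centroid.

    This is the size measure removed by the scaling step of the
    superimposition.
    """
    pts = _as_points(config)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered ** 2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("all points coincident")
    return size


def _center_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    size = np.sqrt((centered ** 2).sum())
    if size == 0.0:
        raise DegenerateConfigurationError("all points coincident")
    return centered / size, float(size)


def _rotation_angles(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation angle of each centered shape onto ``target``."""
    dots = np.einsum("nkc,kc->n", shapes, target)
    cross = (shapes[:, :, 0] * target[None, :, 1]
             - shapes[:, :, 1] * target[None, :, 0]).sum(axis=1)
    return np.arctan2(cross, dots)


def _rotate(shapes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    x, y = shapes[..., 0], shapes[..., 1]
    if shapes.ndim == 3:
        c, s = c[:, None], s[:, None]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


@dataclass
class PairAlignment:
    """Least-squares similarity fit of a source onto a target."""

    rotation: float           # radians, counter-clockwise
    scale: float
    translation: np.ndarray   # (2,)
    aligned: np.ndarray       # (k, 2) transformed source
    residual: float           # minimal sum of squared point distances


def align_pair(source, target) -> PairAlignment:
    """Fit source onto target over rotation, scale and translation.

    Minimizes the sum of squared point distances; the fitted rotation is
    always proper (no reflection).
    """
    a, b = _as_points(source), _as_points(target)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - mu_a, b - mu_b
    na2 = (ac ** 2).sum()
    if na2 == 0 or (bc ** 2).sum() == 0:
        raise DegenerateConfigurationError("degenerate configuration")
    dot = (ac * bc).sum()
    cross = (ac[:, 0] * bc[:, 1] - ac[:, 1] * bc[:, 0]).sum()
    angle = float(np.arctan2(cross, dot))
    beta = float(np.hypot(dot, cross) / na2)
    rotated = _rotate(ac[None], np.array([angle]))[0]
    aligned = beta * rotated + mu_b
    residual = float(max((bc ** 2).sum() - beta ** 2 * na2, 0.0))
    translation = mu_b - beta * _rotate(mu_a[None, None], np.array([angle]))[0, 0]
    return PairAlignment(rotation=angle, scale=beta,
                         translation=translation, aligned=aligned,
                         residual=residual)


@dataclass
class AlignedEnsemble:
    """Product of a generalized Procrustes fit.

    ``aligned`` holds the superimposed shapes (centered at the origin,
    unit centroid size under the default partial-Procrustes scaling);
    ``consensus`` is their coordinate-wise mean.
    """

    aligned: np.ndarray            # (n, k, 2)
    consensus: np.ndarray          # (k, 2) mean of aligned
    centroid_sizes: np.ndarray     # (n,)
    iterations: int
    final_change: float
    converged: bool = True
    derotated: bool = False
    reference_angle: float | None = None
    specimen_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2k) matrix (x1 y1 x2 y2 ...)."""
        return self.aligned.reshape(self.n, -1)


def gpa(configs, tol: float = 1e-8, max_iter: int = 100,
        scaling: str = "partial",
        specimen_ids: Sequence[str] | None = None) -> AlignedEnsemble:
    """Generalized Procrustes superimposition of n configurations.

    Iterates rotate-to-consensus / recompute-consensus from a first-
    configuration start until the root-mean-square change of the
    (unit-size) consensus drops below ``tol``.

    Parameters
    ----------
    configs : sequence of LandmarkConfiguration, or (n, k, 2) array
    scaling : "partial" keeps every shape at unit centroid size;
        "full" additionally fits a per-specimen scale to the consensus.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, float)
    else:
        configs = list(configs)
        if specimen_ids is None and configs and isinstance(
                configs[0], LandmarkConfiguration):
            specimen_ids = [c.specimen_id for c in configs]
        arr = configs_to_array(configs)
    n, k = arr.shape[0], arr.shape[1]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if scaling not in ("partial", "full"):
        raise ValueError("scaling must be 'partial' or 'full'")

    centered = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered ** 2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        bad = int(np.where(sizes == 0)[0][0])
        raise DegenerateConfigurationError(
            f"configuration {bad} has coincident points")
    shapes = centered / sizes[:, None, None]

    consensus = shapes[0].copy()
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        angles = _rotation_angles(shapes, consensus)
        shapes = _rotate(shapes, angles)
        if scaling == "full":
            betas = np.einsum("nkc,kc->n", shapes, consensus) / (
                (shapes ** 2).sum(axis=(1, 2)))
            shapes = shapes * betas[:, None, None]
        new_cons = shapes.mean(axis=0)
        new_cons -= new_cons.mean(axis=0)
        new_cons /= np.sqrt((new_cons ** 2).sum())
        change = float(np.sqrt(((new_cons - consensus) ** 2).mean()))
        consensus = new_cons
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"GPA stopped at max_iter={max_iter} with consensus change "
            f"{change:.3g} > tol {tol:.3g}", ConvergenceWarning)
    mean_shape = shapes.mean(axis=0)
    return AlignedEnsemble(
        aligned=shapes, consensus=mean_shape, centroid_sizes=sizes,
        iterations=it, final_change=change, converged=converged,
        specimen_ids=list(specimen_ids) if specimen_ids else None)


def procrustes_distance(a, b, atol: float = 1e-6) -> float:
    """Partial Procrustes distance between two normalized shapes.

    Both inputs must already be centered and at unit centroid size
    (within ``atol``); align or normalize first otherwise.
    """
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ValueError("shape mismatch")
    for name, p in (("a", pa), ("b", pb)):
        if np.abs(p.mean(axis=0)).max() > atol:
            raise ValueError(
                f"shape {name} is not centered; run gpa/normalize first")
        if abs(np.sqrt((p ** 2).sum()) - 1.0) > atol:
            raise ValueError(
                f"shape {name} does not have unit centroid size; "
                "normalize first")
    dot = (pa * pb).sum()
    cross = (pa[:, 0] * pb[:, 1] - pa[:, 1] * pb[:, 0]).sum()
    # rotate explicitly rather than via 2 - 2*cov: avoids catastrophic
    # cancellation for nearly identical shapes
    angle = np.arctan2(cross, dot)
    rotated = _rotate(pa[None], np.array([angle]))[0]
    return float(np.sqrt(((rotated - pb) ** 2).sum()))


def normalize_shape(points) -> np.ndarray:
    """Center a configuration and scale it to unit centroid size."""
    shape, _ = _center_scale(_as_points(points))
    return shape


# ---------------------------------------------------------------------------
# articulation derotation
# ---------------------------------------------------------------------------

def _triple_from(scheme_or_triple):
    if isinstance(scheme_or_triple, PointScheme):
        trip = scheme_or_triple.derotation_triple
        if trip is None:
            raise ValueError("scheme has no derotation triple")
        return trip
    trip = tuple(int(v) for v in scheme_or_triple)
    if len(trip) != 3:
        raise ValueError("derotation triple must have 3 indices")
    return trip


def measure_angle(config, scheme_or_triple) -> float:
    """Signed angle (radians) at the vertex: ray_a → vertex → ray_b."""
    pts = _as_points(config)
    ia, iv, ib = _triple_from(scheme_or_triple)
    ra, rb = pts[ia] - pts[iv], pts[ib] - pts[iv]
    if (ra == 0).all() or (rb == 0).all():
        raise DegenerateConfigurationError(
            f"ray point coincident with vertex (triple {(ia, iv, ib)})")
    return float(np.arctan2(ra[0] * rb[1] - ra[1] * rb[0],
                            ra[0] * rb[0] + ra[1] * rb[1]))


def derotate(config, scheme_or_triple, reference_angle: float):
    """Rotate the post-vertex subset so the triple angle equals a reference.

    Points with index strictly greater than the vertex (the neck/head
    set, which shares the vertex with the croup/back set) are rotated
    rigidly about the vertex; the rest of the outline is untouched, so
    the subset's internal geometry is preserved exactly.
    """
    ia, iv, ib = _triple_from(scheme_or_triple)
    pts = _as_points(config).copy()
    current = measure_angle(pts, (ia, iv, ib))
    delta = reference_angle - current
    vertex = pts[iv].copy()
    rot = _rotate((pts[iv + 1:] - vertex)[None], np.array([delta]))[0]
    pts[iv + 1:] = rot + vertex
    if isinstance(config, LandmarkConfiguration):
        from dataclasses import replace
        return replace(config, points=pts)
    return pts


def derotate_sample(configs, scheme_or_triple,
                    reference_angle: float | None = None):
    """Derotate every configuration to a common angle.

    The default reference is the circular mean of the measured angles
    over the sample, so derotation removes the articulation variance
    without biasing the mean posture.

    Returns ``(derotated configs, reference_angle)``.
    """
    trip = _triple_from(scheme_or_triple)
    configs = list(configs)
    angles = np.array([measure_angle(c, trip) for c in configs])
    if reference_angle is None:
        reference_angle = float(np.arctan2(np.sin(angles).mean(),
                                           np.cos(angles).mean()))
    out = [derotate(c, trip, reference_angle) for c in configs]
    return out, reference_angle
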