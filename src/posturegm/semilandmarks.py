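"""Thin-plate splines and bending-energy semilandmark sliding.

A thin-plate spline (TPS) interpolates a deformation of the plane that
maps a reference configuration onto a target, with radial kernel
U(r) = r² log r².  Its non-affine part has a quadratic cost — the
bending energy — given by the k × k matrix B obtained from the inverted
TPS system; dᵀ B d measures how non-affine a displacement field d is.

Semilandmarks mark positions along a homologous curve whose exact
along-curve spacing is arbitrary.  Sliding moves each semilandmark along
its local tangent (the chord through its two neighbours; a one-sided
chord at curve ends) so that the deformation from the sample consensus
to the specimen has minimal bending energy.  Because the displacement is
linear in the sliding amounts, each specimen's optimal slide is a small
closed-form linear solve, and iterating slide → re-superimpose removes
the effect of the arbitrary initial spacing of points along the curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConvergenceWarning, DegenerateConfigurationError
from .io_formats import PointScheme, SLIDER
from .superimposition import AlignedEnsemble, gpa

__all__ = [
    "TpsWarp", "SlidingResult", "tps_kernel", "bending_energy_matrix",
    "tps_warp", "bending_energy", "slide_once", "slide_until_converged",
]

logger = logging.getLogger(__name__)


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """Radial kernel U(r) = r² log r² evaluated from squared distances."""
    r2 = np.asarray(r2, float)
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def _tps_system(reference: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    k = reference.shape[0]
    diff = reference[:, None, :] - reference[None, :, :]
    r2 = (diff ** 2).sum(axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(r2[off] == 0):
        ii, jj = np.where((r2 == 0) & off)
        pair = (int(ii[0]), int(jj[0]))
        raise DegenerateConfigurationError(
            f"coincident reference points {pair}: singular TPS kernel")
    K = tps_kernel(r2)
    if ridge:
        K = K + ridge * np.eye(k)
    P = np.column_stack([np.ones(k), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def bending_energy_matrix(reference, *, regularize: bool = False,
                          ridge: float = 1e-8) -> np.ndarray:
    """Bending-energy matrix B of a 2D reference configuration.

    B is the upper-left k × k block of the inverted TPS system: symmetric,
    positive semidefinite, and zero on every affine displacement field
    (its null space is spanned by 1, x and y).  For k = 3 the matrix is
    identically zero — three points only admit affine warps.

    ``regularize`` adds a small ridge to the kernel block so collinear
    references (singular system) still invert; the event is logged.
    """
    reference = np.asarray(reference, float)
    k = reference.shape[0]
    if k < 3:
        raise ValueError("need at least 3 reference points")
    if k == 3:
        # exact: the affine space is all of R^3 per coordinate
        return np.zeros((3, 3))
    L = _tps_system(reference)
    cond = np.linalg.cond(L)
    if cond < 1e12:
        Linv = np.linalg.inv(L)
    elif regularize:
        # collinear references leave the system rank-deficient (a
        # degenerate affine basis); the pseudoinverse of the ridged
        # system still annihilates the surviving affine fields
        logger.info("TPS system ill-conditioned (cond %.1e); using "
                    "ridge %.1e + pseudoinverse", cond, ridge)
        Linv = np.linalg.pinv(_tps_system(reference, ridge=ridge))
    else:
        raise DegenerateConfigurationError(
            "singular TPS system (collinear reference?); pass "
            "regularize=True to add a small kernel ridge")
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)


def bending_energy(B: np.ndarray, displacement: np.ndarray) -> float:
    """Quadratic form dᵀBd summed over the x and y displacement fields."""
    d = np.asarray(displacement, float)
    if d.ndim == 2:  # (k, 2)
        return float(np.einsum("kc,kl,lc->", d, B, d))
    return float(d @ B @ d)


@dataclass
class TpsWarp:
    """Interpolating thin-plate-spline map from a reference to a target."""

    reference: np.ndarray       # (k, 2)
    affine_part: np.ndarray     # (2, 3): rows [c, a_x, a_y] per coordinate
    nonaffine_weights: np.ndarray  # (k, 2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        diff = pts[:, None, :] - self.reference[None, :, :]
        U = tps_kernel((diff ** 2).sum(axis=2))          # (m, k)
        ones = np.column_stack([np.ones(len(pts)), pts])  # (m, 3)
        return ones @ self.affine_part.T + U @ self.nonaffine_weights


def tps_warp(reference, target) -> TpsWarp:
    """Fit the TPS interpolant mapping reference points onto target points.

    The warp reproduces every target point exactly and its non-affine
    weights satisfy the orthogonality side conditions (PᵀW = 0).
    """
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError("reference/target point count mismatch")
    k = reference.shape[0]
    L = _tps_system(reference)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError:
        raise DegenerateConfigurationError(
            "singular TPS system; jitter the reference points or add a "
            "regularizing ridge") from None
    return TpsWarp(reference=reference, affine_part=sol[k:].T,
                   nonaffine_weights=sol[:k])


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

@dataclass
class SlidingResult:
    """Outcome of semilandmark sliding."""

    ensemble: AlignedEnsemble          # slid (and re-superimposed) shapes
    displacements: np.ndarray          # (n, m) signed slide amounts (last pass)
    bending_energy_trace: list[float]  # total energy after each pass
    converged: bool = True
    iterations: int = 0


def _tangents(shapes: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Unit tangent of each slider in each specimen: (n, m, 2).

    The tangent is the chord through the slider's two neighbours; for a
    one-sided triple (before == after) it is the chord from the slider
    to that single neighbour.
    """
    before, mid, after = triples[:, 0], triples[:, 1], triples[:, 2]
    chord = shapes[:, after, :] - shapes[:, before, :]
    one_sided = before == after
    if one_sided.any():
        chord[:, one_sided, :] = (shapes[:, after[one_sided], :]
                                  - shapes[:, mid[one_sided], :])
    norm = np.linalg.norm(chord, axis=2)
    if np.any(norm == 0):
        n_i, m_i = np.argwhere(norm == 0)[0]
        raise DegenerateConfigurationError(
            f"zero-length neighbour chord at specimen {n_i}, slider "
            f"{int(triples[m_i, 1])}")
    return chord / norm[:, :, None]


def slide_once(ensemble: AlignedEnsemble, scheme: PointScheme,
               criterion: str = "bending") -> SlidingResult:
    """One bending-energy-minimizing slide of every specimen's sliders.

    For specimen displacement d = x − consensus and slider tangents u,
    sliding x → x + U·t with t solving min_t (d + U t)ᵀ B (d + U t)
    gives t = −(UᵀBU)⁻¹ UᵀB d, where B acts separately on the x and y
    fields.  With a single nonzero direction per slider this reduces to
    M t = −g with M = B[s, s] ∘ (u·uᵀ) and g_j = u_j · (Bd)[s_j].
    Non-slider points are untouched; the returned configurations are not
    re-superimposed.

    ``criterion="procrustes"`` instead minimizes the Procrustes distance
    to the consensus (each slider independently projects its residual
    onto the tangent); the bending-energy criterion is the default.
    """
    if scheme.n_points != ensemble.k:
        raise ValueError(
            f"scheme is for {scheme.n_points} points, ensemble has "
            f"{ensemble.k}")
    triples = scheme.slider_triples
    if len(triples) == 0:
        raise ValueError("scheme has no sliders")
    sl = triples[:, 1]
    B = bending_energy_matrix(ensemble.consensus, regularize=True)
    shapes = ensemble.aligned
    n = shapes.shape[0]
    T = _tangents(shapes, triples)                      # (n, m, 2)
    d = shapes - ensemble.consensus[None]               # (n, k, 2)
    if criterion == "procrustes":
        t = -np.einsum("nmc,nmc->nm", d[:, sl, :], T)
    elif criterion == "bending":
        Bd = np.einsum("kl,nlc->nkc", B, d)             # (n, k, 2)
        G = np.einsum("nmc,npc->nmp", T, T)             # gram of tangents
        M = B[np.ix_(sl, sl)][None] * G                 # (n, m, m)
        g = np.einsum("nmc,nmc->nm", Bd[:, sl, :], T)   # (n, m)
        # ridge for singular systems (e.g. collinear consensus regions)
        eye = np.eye(len(sl))
        try:
            t = -np.linalg.solve(M + 1e-12 * eye[None], g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            t = np.stack([-np.linalg.lstsq(M[i], g[i], rcond=None)[0]
                          for i in range(n)])
    else:
        raise ValueError("criterion must be 'bending' or 'procrustes'")
    new = shapes.copy()
    new[:, sl, :] += t[:, :, None] * T
    energy = float(sum(
        bending_energy(B, new[i] - ensemble.consensus) for i in range(n)))
    new_ens = replace(ensemble, aligned=new,
                      consensus=new.mean(axis=0))
    return SlidingResult(ensemble=new_ens, displacements=t,
                         bending_energy_trace=[energy], iterations=1)


def slide_until_converged(configs, scheme: PointScheme,
                          tol: float = 1e-6, max_iter: int = 10,
                          gpa_tol: float = 1e-8,
                          update_consensus: bool = True,
                          criterion: str = "bending") -> SlidingResult:
    """Alternate GPA and bending-energy sliding until sliders stop moving.

    Starts from a generalized Procrustes fit of the raw configurations,
    then repeats slide → re-superimpose (recomputing the consensus each
    round unless ``update_consensus`` is False, which freezes the first
    consensus as the sliding reference) until the RMS slider movement
    falls below ``tol`` in shape units.

    With no sliders in the scheme this reduces exactly to plain GPA.
    """
    ensemble = gpa(configs, tol=gpa_tol)
    if len(scheme.slider_triples) == 0:
        return SlidingResult(ensemble=ensemble,
                             displacements=np.zeros((ensemble.n, 0)),
                             bending_energy_trace=[], converged=True,
                             iterations=0)
    trace: list[float] = []
    frozen_consensus = ensemble.consensus.copy()
    t = np.zeros((ensemble.n, len(scheme.slider_triples)))
    it = 0
    converged = False
    prev_energy = np.inf
    for it in range(1, max_iter + 1):
        ref = ensemble if update_consensus else replace(
            ensemble, consensus=frozen_consensus)
        step = slide_once(ref, scheme, criterion=criterion)
        energy = step.bending_energy_trace[0]
        if energy > prev_energy:
            # re-superimposition noise floor reached: a further pass no
            # longer lowers the total energy, so keep the previous state
            converged = True
            it -= 1
            break
        prev_energy = energy
        t = step.displacements
        trace.append(energy)
        rms = float(np.sqrt((t ** 2).mean()))
        ensemble = gpa(step.ensemble.aligned, tol=gpa_tol)
        if rms < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sliding stopped at max_iter={max_iter} (last RMS movement "
            f"{np.sqrt((t ** 2).mean()):.3g} > tol {tol:.3g})",
            ConvergenceWarning)
    return SlidingResult(ensemble=ensemble, displacements=t,
                         bending_energy_trace=trace, converged=converged,
                         iterations=it)
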