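"""Shape PCA, component retention and deformation grids.

After superimposition (and sliding, when the method uses
semilandmarks) the aligned coordinates live in a linear shape space;
principal component analysis of their covariance summarizes the main
modes of postural variation.  Components are retained while they
explain at least a threshold share of the variance (10% by default,
so typically the first three).  A PC's effect on posture is shown by
reconstructing the shape at an extreme score and mapping a regular
lattice through the thin-plate-spline warp from the consensus to that
shape — the classic deformation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .semilandmarks import tps_warp
from .superimposition import AlignedEnsemble

__all__ = ["ShapePCA", "DeformationGrid", "shape_pca",
           "retained_components", "pc_extreme_shape", "deformation_grid"]


@dataclass
class ShapePCA:
    """PCA of Procrustes coordinates about the consensus.

    ``loadings`` rows are orthonormal 2k-vectors (x1 y1 x2 y2 ... order);
    ``scores[i, j]`` is specimen i's coordinate on component j;
    ``percent_variance`` sums to 100 over the full spectrum.
    """

    loadings: np.ndarray          # (r, 2k)
    scores: np.ndarray            # (n, r)
    percent_variance: np.ndarray  # (r,)
    consensus: np.ndarray         # (k, 2)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]


def shape_pca(ensemble: AlignedEnsemble) -> ShapePCA:
    """Principal components of the aligned coordinates.

    Uses the singular value decomposition of the centered data matrix
    (equivalent to the eigen-decomposition of the coordinate
    covariance).  At most min(n − 1, 2k − 4) components are kept: the
    superimposition removes two translations, one rotation and the
    scale, so the shape space has 2k − 4 dimensions.  A deterministic
    sign convention makes each loading's largest-magnitude entry
    positive.
    """
    X = ensemble.flat()
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0.0:
        raise ValueError("no shape variation: all aligned shapes identical")
    r = min(n - 1, p - 4)
    r = max(r, 1)
    loadings = Vt[:r]
    scores = U[:, :r] * s[:r]
    # sign convention: largest-|entry| of each loading is positive
    flip = np.sign(loadings[np.arange(r),
                            np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    percent = 100.0 * (s[:r] ** 2) / total
    return ShapePCA(loadings=loadings, scores=scores,
                    percent_variance=percent,
                    consensus=mean.reshape(-1, 2))


def retained_components(pca: ShapePCA,
                        threshold_percent: float = 10.0,
                        max_components: int | None = None) -> list[int]:
    """Leading components explaining at least ``threshold_percent``.

    Retention stops at the first component below the threshold
    (components beyond it are discarded even if one later happens to
    exceed it); the first component is always kept.  ``max_components``
    caps the list (the method-comparison analysis uses at most 3).
    """
    if not 0.0 < threshold_percent < 100.0:
        raise ValueError("threshold must be in (0, 100)")
    kept = [0]
    for j in range(1, pca.n_components):
        if pca.percent_variance[j] >= threshold_percent:
            kept.append(j)
        else:
            break
    if max_components is not None:
        kept = kept[:max_components]
    return kept


def pc_extreme_shape(pca: ShapePCA, component: int,
                     score: float) -> np.ndarray:
    """Shape at a given score along one component: consensus + s·loading."""
    if not 0 <= component < pca.n_components:
        raise IndexError(
            f"component {component} out of range 0..{pca.n_components - 1}")
    return pca.consensus + score * pca.loadings[component].reshape(-1, 2)


@dataclass
class DeformationGrid:
    """A regular lattice and its image under a TPS warp."""

    source: np.ndarray    # (m, m, 2) lattice nodes
    warped: np.ndarray    # (m, m, 2) nodes mapped through the warp
    magnitude: float

    def as_table(self) -> np.ndarray:
        """Rows (node_row, node_col, x_src, y_src, x_warp, y_warp)."""
        m = self.source.shape[0]
        rows, cols = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        return np.column_stack([
            rows.ravel(), cols.ravel(),
            self.source.reshape(-1, 2), self.warped.reshape(-1, 2)])


def deformation_grid(reference, target, grid_density: int = 24,
                     magnitude: float = 1.0,
                     margin: float = 0.15) -> DeformationGrid:
    """Map a square lattice through the reference → target TPS warp.

    The lattice covers the reference bounding box expanded by
    ``margin`` on each side; the warp is fitted to
    reference + magnitude × (target − reference), so magnitude 0 leaves
    the lattice exactly unchanged and magnitude 1 shows the full
    deformation.
    """
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError("reference/target shape mismatch")
    if grid_density < 2:
        raise ValueError("grid_density must be at least 2")
    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    gx = np.linspace(lo[0], hi[0], grid_density)
    gy = np.linspace(lo[1], hi[1], grid_density)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    source = np.stack([xx, yy], axis=-1)
    if magnitude == 0.0:
        return DeformationGrid(source=source, warped=source.copy(),
                               magnitude=0.0)
    warp = tps_warp(reference, reference + magnitude * (target - reference))
    warped = warp(source.reshape(-1, 2)).reshape(source.shape)
    return DeformationGrid(source=source, warped=warped,
                           magnitude=float(magnitude))
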