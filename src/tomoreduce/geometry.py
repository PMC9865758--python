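"""Parallel-beam strip geometry, forward projection and its exact adjoint.

The acquisition model: a parallel beam illuminates the sample and an array of
``J`` sensors of width ``d`` records, at each of ``K`` rotation angles
``phi_k = k * delta_phi``, the integral of the absorption coefficient over the
strip of width ``d`` in front of each sensor.  The object lives on an ``N x N``
pixel grid (pixel size 1) with the physical origin at the grid centre, x to the
right and y upward; rotating the sample by ``phi`` is realised by rotating the
strip frame by ``-phi``.

Strip/pixel intersection areas are computed by sub-pixel supersampling
(``n_subpixel**2`` samples per pixel, default 4x4).  Per-angle sparse weight
matrices are memoized, so the full ``KJ x N^2`` operator is never materialised;
:func:`assemble_matrix` builds it explicitly only for small instances, as an
oracle and for the dense linear-reduction path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ScanGeometry",
    "NoiseModel",
    "StripRow",
    "strip_row",
    "strip_matrix",
    "forward_project",
    "adjoint_project",
    "assemble_matrix",
    "whiten",
    "omega_mask",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition description.

    Parameters
    ----------
    J : int
        Number of sensors in the array.
    K : int
        Number of rotation angles.
    d : float
        Sensor (strip) width in pixel units.  Strips are contiguous: sensor
        ``j`` (0-based) covers perpendicular offsets
        ``s in [-J*d/2 + j*d, -J*d/2 + (j+1)*d)``.
    delta_phi : float
        Angular step in radians; defaults to ``pi / K`` so the sample turns
        through half a revolution.
    N : int
        Image side in pixels; defaults to ``J``.
    omega_radius : float
        Radius of the reconstruction disc Omega; defaults to ``N / 2``.
        The object is assumed supported inside Omega, which must be covered
        by the sensor span at every angle.
    n_subpixel : int
        Supersampling density per pixel axis for strip-weight computation.
    """

    J: int
    K: int
    d: float = 1.0
    delta_phi: float = None  # type: ignore[assignment]
    N: int = None  # type: ignore[assignment]
    omega_radius: float = None  # type: ignore[assignment]
    n_subpixel: int = 4

    def __post_init__(self) -> None:
        if self.J < 1 or self.K < 1:
            raise ValueError("J and K must be positive integers")
        if self.d <= 0:
            raise ValueError("sensor width d must be positive")
        if self.delta_phi is None:
            object.__setattr__(self, "delta_phi", math.pi / self.K)
        if self.delta_phi <= 0:
            raise ValueError("delta_phi must be positive")
        if self.N is None:
            object.__setattr__(self, "N", self.J)
        if self.N < 1:
            raise ValueError("image side N must be positive")
        if self.omega_radius is None:
            object.__setattr__(self, "omega_radius", self.N / 2)
        if self.omega_radius <= 0 or self.omega_radius > self.N / 2 + 1e-12:
            raise ValueError("omega_radius must lie in (0, N/2]")
        if self.n_subpixel < 1:
            raise ValueError("n_subpixel must be >= 1")
        if self.K * self.delta_phi < math.pi - 1e-9:
            raise ValueError(
                "angular coverage K*delta_phi must reach at least pi "
                "(the sample rotates by at least 180 degrees)"
            )
        if self.d * self.J < 2 * self.omega_radius - 1e-9:
            warnings.warn(
                "sensor span d*J does not cover the reconstruction disc; "
                "parts of Omega are outside the ray paths",
                stacklevel=2,
            )

    @property
    def angles(self) -> np.ndarray:
        """The K rotation angles ``phi_k = k * delta_phi`` (radians)."""
        return np.arange(self.K) * self.delta_phi

    @property
    def n_pixels(self) -> int:
        return self.N * self.N


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean measurement-noise description.

    Either white noise with standard deviation ``sigma`` (covariance
    ``sigma**2 * I``) or a diagonal covariance given by per-element
    ``variances``.
    """

    sigma: float = None  # type: ignore[assignment]
    variances: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.sigma is None) == (self.variances is None):
            raise ValueError("give exactly one of sigma or variances")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.variances is not None:
            v = np.asarray(self.variances, dtype=float)
            if np.any(v < 0):
                raise ValueError("variances must be non-negative")
            object.__setattr__(self, "variances", tuple(v.ravel().tolist()))

    @property
    def kind(self) -> str:
        return "white" if self.sigma is not None else "diagonal"

    def variance_vector(self, m: int) -> np.ndarray:
        """Diagonal of the covariance as a length-``m`` vector."""
        if self.sigma is not None:
            return np.full(m, self.sigma**2)
        v = np.asarray(self.variances, dtype=float)
        if v.size != m:
            raise ValueError(f"expected {m} variances, got {v.size}")
        return v


@dataclass
class StripRow:
    """One row of the strip-projection operator: the pixels a strip touches.

    ``indices`` are (row, col) pixel coordinates, ``weights`` the intersection
    areas of each pixel with the strip, ``norm_sq`` the cached squared
    Euclidean norm of the row.
    """

    indices: np.ndarray
    weights: np.ndarray
    norm_sq: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.norm_sq is None:
            self.norm_sq = float(np.sum(self.weights**2))


@lru_cache(maxsize=None)
def _subsample_grid(geom: ScanGeometry):
    """Physical coordinates of all sub-pixel sample points, plus pixel ids."""
    N, n = geom.N, geom.n_subpixel
    half = (N - 1) / 2
    centers = np.arange(N) - half
    off = (np.arange(n) + 0.5) / n - 0.5
    # per-axis supersampled coordinates, shape (N*n,)
    cx = (centers[:, None] + off[None, :]).ravel()
    # x varies with column, y decreases with row
    xs = np.broadcast_to(cx[None, :], (N * n, N * n)).ravel()
    ys = np.broadcast_to(-cx[:, None], (N * n, N * n)).ravel()
    # pixel index of each sample point, row-major raveling of (row, col)
    pr = np.repeat(np.arange(N), n)
    pix = (pr[:, None] * N + pr[None, :]).ravel()
    return xs, ys, pix


@lru_cache(maxsize=256)
def strip_matrix(geom: ScanGeometry, k: int) -> sp.csr_matrix:
    """Sparse ``J x N^2`` matrix of strip weights at angle index ``k``.

    Entry (j, p) is the area of pixel p intersected with strip ``D_{k,j}``,
    estimated by supersampling.  Memoized per (geometry, angle).
    """
    if not 0 <= k < geom.K:
        raise IndexError(f"angle index {k} out of range [0, {geom.K})")
    xs, ys, pix = _subsample_grid(geom)
    phi = k * geom.delta_phi
    # offset along the axis perpendicular to the ray direction, in the strip
    # frame rotated by -phi (at phi=0 strips are vertical pixel columns)
    s = xs * math.cos(phi) + ys * math.sin(phi)
    idx = np.floor((s + geom.J * geom.d / 2) / geom.d).astype(np.int64)
    ok = (idx >= 0) & (idx < geom.J)
    w = 1.0 / geom.n_subpixel**2
    mat = sp.coo_matrix(
        (np.full(np.count_nonzero(ok), w), (idx[ok], pix[ok])),
        shape=(geom.J, geom.n_pixels),
    )
    return mat.tocsr()


def strip_row(geom: ScanGeometry, k: int, j: int) -> StripRow:
    """Weights of pixels intersecting strip ``D_{k,j}`` (0-based indices)."""
    if not 0 <= j < geom.J:
        raise IndexError(f"sensor index {j} out of range [0, {geom.J})")
    row = strip_matrix(geom, k).getrow(j)
    cols = row.indices
    coords = np.stack([cols // geom.N, cols % geom.N], axis=1)
    return StripRow(indices=coords, weights=row.data.copy())


def _check_image(f: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (geom.N, geom.N):
        raise ValueError(f"image shape {f.shape} != ({geom.N}, {geom.N})")
    return f


def _check_sinogram(s: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (geom.K, geom.J):
        raise ValueError(f"sinogram shape {s.shape} != ({geom.K}, {geom.J})")
    return s


def forward_project(f: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Strip-integral forward projection ``A f``: the noiseless sinogram.

    Returns a ``K x J`` array whose entry (k, j) is the integral of ``f``
    over strip ``D_{k,j}``.
    """
    f = _check_image(f, geom)
    fv = f.ravel()
    g = np.empty((geom.K, geom.J))
    for k in range(geom.K):
        g[k] = strip_matrix(geom, k) @ fv
    return g


def adjoint_project(s: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Exact adjoint ``A* s``: pixel p accumulates ``sum w_{k,j}(p) s_{k,j}``.

    This is the exact transpose of :func:`forward_project`, so the adjoint
    identity ``<A f, s> = <f, A* s>`` holds to rounding error.
    """
    s = _check_sinogram(s, geom)
    acc = np.zeros(geom.n_pixels)
    for k in range(geom.K):
        acc += strip_matrix(geom, k).T @ s[k]
    return acc.reshape(geom.N, geom.N)


def assemble_matrix(geom: ScanGeometry, cap: int = 10**7) -> sp.csr_matrix:
    """Explicit ``KJ x N^2`` operator, rows raveled angle-major: i = k*J + j.

    Only for small instances (oracle and dense reduction); refuses when
    ``K*J*N**2`` exceeds ``cap``.
    """
    if geom.K * geom.J * geom.n_pixels > cap:
        raise ValueError(
            f"instance K*J*N^2 = {geom.K * geom.J * geom.n_pixels} exceeds "
            f"cap {cap}; use the matrix-free operators instead"
        )
    return sp.vstack([strip_matrix(geom, k) for k in range(geom.K)]).tocsr()


def whiten(s: np.ndarray, noise: NoiseModel) -> tuple[np.ndarray, np.ndarray]:
    """Scale a sinogram to unit noise variance.

    Returns the element-wise scaled sinogram and the scale factors (to be
    applied to the corresponding operator rows).  White noise with sigma
    gives a uniform scale ``1/sigma``.
    """
    s = np.asarray(s, dtype=float)
    var = noise.variance_vector(s.size).reshape(s.shape)
    if np.any(var <= 0):
        raise ValueError("whitening requires strictly positive noise variances")
    scales = 1.0 / np.sqrt(var)
    return s * scales, scales


def omega_mask(geom: ScanGeometry) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside the disc Omega."""
    N = geom.N
    half = (N - 1) / 2
    c = np.arange(N) - half
    X, Y = np.meshgrid(c, -c, indexing="xy")
    return X**2 + Y**2 <= geom.omega_radius**2
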