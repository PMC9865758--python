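"""Projected iterative measurement reduction: Kaczmarz, Landweber, SART.

All methods start from the zero image and enforce non-negativity by Euclidean
projection onto the cone after each update, so every returned image has
minimum >= 0 exactly.  The per-ray Kaczmarz step for row ``a_i`` is

    f <- max(f + lam * (xi_i - <a_i, f>) / ||a_i||^2 * a_i, 0),

with relaxation ``0 < lam < 2`` (values at or above 2 no longer contract the
distance to the row's hyperplane and are flagged).  The improved variant
processes one rotation angle per outer iteration, computing every sensor's
correction against the same current estimate and applying their sum at once
(rays at one angle do not overlap, so their corrections are independent);
angles are visited in golden-ratio order so that consecutive angles are as
spread out as possible.  The Landweber (gradient-descent) variant iterates
``f <- max(f - lam * A*(A f - xi), 0)`` with ``lam < 2 / ||A||^2``, the norm
coming from power iteration on ``A* A``.  SART is included as the standard
baseline: corrections normalized by the ray (row) sums and pixel (column)
sums of the angle's weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import ScanGeometry, _check_sinogram, strip_matrix

__all__ = [
    "IterationControl",
    "IterationTrace",
    "golden_ratio_order",
    "kaczmarz_row_update",
    "run_mr_kaczmarz_basic",
    "run_mr_kaczmarz",
    "run_mr_gd",
    "run_sart",
    "operator_norm",
    "operator_norm_matvec",
]

_INV_GOLDEN = 2.0 / (1.0 + math.sqrt(5.0))  # 1/phi = 0.618...


@dataclass
class IterationControl:
    """Knobs shared by the iterative solvers.

    ``lam`` and ``n_iter`` default per method when left as None (Kaczmarz
    variants: lam=0.5; Landweber: lam = 1/||A||^2; n_iter = K*J single-row
    updates for the basic Kaczmarz, K angle visits otherwise).  ``ordering``
    None picks the method's natural default (golden for the improved
    Kaczmarz, sequential for the rest).  ``trace_every`` controls how often
    the full data residual is recorded (None: every angle-level iteration,
    every J row-updates for the basic version).  ``tol`` > 0 stops early when
    the update norm falls below it.
    """

    lam: float = None  # type: ignore[assignment]
    n_iter: int = None  # type: ignore[assignment]
    ordering: str = None  # type: ignore[assignment]
    seed: int = 0
    tol: float = 0.0
    trace_every: int = None  # type: ignore[assignment]

    def resolved_lam(self, default: float, upper: float | None = None) -> float:
        lam = default if self.lam is None else self.lam
        if lam <= 0:
            raise ValueError("step size lam must be positive")
        if upper is not None and lam >= upper:
            raise ValueError(f"step size lam={lam} must be below {upper}")
        return lam


@dataclass
class IterationTrace:
    """Per-iteration diagnostics recorded every ``trace_every`` iterations."""

    residuals: list = field(default_factory=list)
    negatives: list = field(default_factory=list)
    iterations: list = field(default_factory=list)


def golden_ratio_order(K: int) -> np.ndarray:
    """Deterministic golden-ratio permutation of angle indices 0..K-1.

    Visits index ``(m * g) mod K`` with stride ``g = round(K / phi)`` adjusted
    to the nearest integer coprime with K, spreading consecutive visits as far
    apart as possible.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.array([0])
    g = int(round(K * _INV_GOLDEN))
    for delta in _alternating():
        cand = g + delta
        if 1 <= cand < K and math.gcd(cand, K) == 1:
            g = cand
            break
    return (np.arange(K) * g) % K


def _alternating():
    yield 0
    d = 1
    while True:
        yield d
        yield -d
        d += 1


def _angle_order(geom: ScanGeometry, ctrl: IterationControl, default: str) -> np.ndarray:
    ordering = ctrl.ordering if ctrl.ordering is not None else default
    if ordering == "golden":
        return golden_ratio_order(geom.K)
    if ordering == "sequential":
        return np.arange(geom.K)
    raise ValueError(f"unknown ordering {ordering!r}")


def _check_kaczmarz_lam(lam: float) -> None:
    if lam <= 0:
        raise ValueError("Kaczmarz step size lam must be positive")
    if lam >= 2:
        warnings.warn(
            f"Kaczmarz step size lam={lam} is outside (0, 2); single-row "
            "updates no longer contract the distance to the hyperplane",
            stacklevel=3,
        )


def kaczmarz_row_update(
    f: np.ndarray, a: np.ndarray, value: float, lam: float
) -> np.ndarray:
    """One relaxed Kaczmarz step toward the hyperplane ``<a, f> = value``.

    Returns ``f + lam * (value - <a, f>) / ||a||^2 * a`` without projection.
    The distance to the hyperplane scales by ``|1 - lam|``, so the step
    contracts exactly for ``0 < lam < 2``.
    """
    a = np.asarray(a, dtype=float)
    norm_sq = float(a @ a)
    if norm_sq == 0.0:
        raise ValueError("row has zero norm")
    return f + (lam * (value - float(a @ f)) / norm_sq) * a


def _residual(f: np.ndarray, s: np.ndarray, geom: ScanGeometry) -> float:
    res = 0.0
    for k in range(geom.K):
        res += float(np.sum((strip_matrix(geom, k) @ f - s[k]) ** 2))
    return math.sqrt(res)


def run_mr_kaczmarz_basic(
    s: np.ndarray, geom: ScanGeometry, ctrl: IterationControl | None = None
) -> tuple[np.ndarray, IterationTrace]:
    """Basic per-ray projected Kaczmarz reduction.

    Cycles over the raveled measurement indices (angle-major; golden ordering
    reorders the angles only), one row per iteration, projecting onto the
    non-negative cone after every update.  ``n_iter`` counts single-row
    updates and defaults to K*J (one use of every measurement).
    """
    ctrl = ctrl or IterationControl()
    s = _check_sinogram(s, geom)
    lam = 0.5 if ctrl.lam is None else ctrl.lam
    _check_kaczmarz_lam(lam)
    n_iter = geom.K * geom.J if ctrl.n_iter is None else ctrl.n_iter
    trace_every = ctrl.trace_every if ctrl.trace_every is not None else geom.J

    angle_order = _angle_order(geom, ctrl, "sequential")
    rows = (angle_order[:, None] * geom.J + np.arange(geom.J)[None, :]).ravel()

    f = np.zeros(geom.n_pixels)
    trace = IterationTrace()
    n_rows = rows.size
    for it in range(n_iter):
        i = rows[it % n_rows]
        k, j = divmod(int(i), geom.J)
        mat = strip_matrix(geom, k)
        start, end = mat.indptr[j], mat.indptr[j + 1]
        cols = mat.indices[start:end]
        a = mat.data[start:end]
        norm_sq = float(a @ a)
        if norm_sq == 0.0:
            continue
        resid = s[k, j] - float(a @ f[cols])
        update = (lam * resid / norm_sq) * a
        g = f[cols] + update
        n_neg = int(np.count_nonzero(g < 0))
        f[cols] = np.maximum(g, 0.0)
        if (it + 1) % trace_every == 0 or it + 1 == n_iter:
            trace.residuals.append(_residual(f, s, geom))
            trace.negatives.append(n_neg)
            trace.iterations.append(it + 1)
        if ctrl.tol > 0 and float(np.linalg.norm(update)) < ctrl.tol:
            break
    return f.reshape(geom.N, geom.N), trace


def _angle_norms_sq(geom: ScanGeometry, k: int) -> np.ndarray:
    mat = strip_matrix(geom, k)
    return np.asarray(mat.multiply(mat).sum(axis=1)).ravel()


def run_mr_kaczmarz(
    s: np.ndarray, geom: ScanGeometry, ctrl: IterationControl | None = None
) -> tuple[np.ndarray, IterationTrace]:
    """Improved projected Kaczmarz reduction: simultaneous per-angle updates.

    One outer iteration visits one angle (golden-ratio order by default),
    computes every sensor's Kaczmarz correction against the same current
    estimate, applies their sum, then projects.  ``n_iter`` counts angle
    visits and defaults to K (each angle once).
    """
    ctrl = ctrl or IterationControl()
    s = _check_sinogram(s, geom)
    lam = 0.5 if ctrl.lam is None else ctrl.lam
    _check_kaczmarz_lam(lam)
    n_iter = geom.K if ctrl.n_iter is None else ctrl.n_iter
    trace_every = ctrl.trace_every if ctrl.trace_every is not None else 1
    order = _angle_order(geom, ctrl, "golden")

    f = np.zeros(geom.n_pixels)
    trace = IterationTrace()
    for it in range(n_iter):
        k = int(order[it % geom.K])
        mat = strip_matrix(geom, k)
        norms = _angle_norms_sq(geom, k)
        resid = s[k] - mat @ f
        coef = np.zeros_like(resid)
        ok = norms > 0
        coef[ok] = lam * resid[ok] / norms[ok]
        g = f + mat.T @ coef
        n_neg = int(np.count_nonzero(g < 0))
        f_next = np.maximum(g, 0.0)
        update_norm = float(np.linalg.norm(f_next - f))
        f = f_next
        if (it + 1) % trace_every == 0 or it + 1 == n_iter:
            trace.residuals.append(_residual(f, s, geom))
            trace.negatives.append(n_neg)
            trace.iterations.append(it + 1)
        if ctrl.tol > 0 and update_norm < ctrl.tol:
            break
    return f.reshape(geom.N, geom.N), trace


def operator_norm_matvec(forward, adjoint, n: int, tol: float = 1e-6,
                         max_iter: int = 200) -> float:
    """Largest singular value via power iteration on ``A* A``.

    ``forward`` and ``adjoint`` act on flat length-``n`` vectors; the start
    vector is all ones (deterministic).
    """
    x = np.ones(n)
    x /= np.linalg.norm(x)
    sigma = 0.0
    for _ in range(max_iter):
        y = adjoint(forward(x))
        norm = float(np.linalg.norm(y))
        if norm == 0.0:
            return 0.0
        sigma_new = math.sqrt(norm)  # ||A*A x|| ~ sigma^2 for unit x
        x = y / norm
        if sigma > 0 and abs(sigma_new - sigma) <= tol * sigma:
            return sigma_new
        sigma = sigma_new
    return sigma


def operator_norm(geom: ScanGeometry, tol: float = 1e-6) -> float:
    """Spectral norm of the strip-projection operator ``A``."""

    def fwd(x: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [strip_matrix(geom, k) @ x for k in range(geom.K)]
        )

    def adj(y: np.ndarray) -> np.ndarray:
        acc = np.zeros(geom.n_pixels)
        for k in range(geom.K):
            acc += strip_matrix(geom, k).T @ y[k * geom.J : (k + 1) * geom.J]
        return acc

    return operator_norm_matvec(fwd, adj, geom.n_pixels, tol=tol)


def run_mr_gd(
    s: np.ndarray,
    geom: ScanGeometry,
    ctrl: IterationControl | None = None,
    nonneg: bool = True,
) -> tuple[np.ndarray, IterationTrace]:
    """Projected gradient-descent (Landweber) reduction.

    Iterates ``f <- max(f - lam * A*(A f - xi), 0)``; ``lam`` defaults to
    ``1 / ||A||^2`` (half its maximal stable value ``2 / ||A||^2``) and values
    at or above the bound are rejected.  ``n_iter`` defaults to K.
    ``nonneg=False`` disables the projection (plain Landweber).
    """
    ctrl = ctrl or IterationControl()
    s = _check_sinogram(s, geom)
    norm_a = operator_norm(geom)
    lam = ctrl.resolved_lam(default=1.0 / norm_a**2, upper=2.0 / norm_a**2)
    n_iter = geom.K if ctrl.n_iter is None else ctrl.n_iter
    trace_every = ctrl.trace_every if ctrl.trace_every is not None else 1

    f = np.zeros(geom.n_pixels)
    trace = IterationTrace()
    for it in range(n_iter):
        grad = np.zeros(geom.n_pixels)
        for k in range(geom.K):
            mat = strip_matrix(geom, k)
            grad += mat.T @ (mat @ f - s[k])
        g = f - lam * grad
        n_neg = int(np.count_nonzero(g < 0))
        f_next = np.maximum(g, 0.0) if nonneg else g
        update_norm = float(np.linalg.norm(f_next - f))
        f = f_next
        if (it + 1) % trace_every == 0 or it + 1 == n_iter:
            trace.residuals.append(_residual(f, s, geom))
            trace.negatives.append(n_neg)
            trace.iterations.append(it + 1)
        if ctrl.tol > 0 and update_norm < ctrl.tol:
            break
    return f.reshape(geom.N, geom.N), trace


def run_sart(
    s: np.ndarray, geom: ScanGeometry, ctrl: IterationControl | None = None
) -> tuple[np.ndarray, IterationTrace]:
    """SART baseline: per-angle corrections normalized by row and column sums.

    One outer iteration visits one angle; the correction for pixel p is
    ``lam / colsum_p * sum_j w_{j,p} (xi_j - <a_j, f>) / rowsum_j`` and
    non-negativity clipping happens once per outer iteration.
    """
    ctrl = ctrl or IterationControl()
    s = _check_sinogram(s, geom)
    lam = 1.0 if ctrl.lam is None else ctrl.lam
    if lam <= 0:
        raise ValueError("step size lam must be positive")
    n_iter = geom.K if ctrl.n_iter is None else ctrl.n_iter
    trace_every = ctrl.trace_every if ctrl.trace_every is not None else 1
    order = _angle_order(geom, ctrl, "sequential")

    f = np.zeros(geom.n_pixels)
    trace = IterationTrace()
    for it in range(n_iter):
        k = int(order[it % geom.K])
        mat = strip_matrix(geom, k)
        row_sum = np.asarray(mat.sum(axis=1)).ravel()
        col_sum = np.asarray(mat.sum(axis=0)).ravel()
        resid = s[k] - mat @ f
        scaled = np.zeros_like(resid)
        ok = row_sum > 0
        scaled[ok] = resid[ok] / row_sum[ok]
        corr = mat.T @ scaled
        okc = col_sum > 0
        corr[okc] /= col_sum[okc]
        corr[~okc] = 0.0
        g = f + lam * corr
        n_neg = int(np.count_nonzero(g < 0))
        f = np.maximum(g, 0.0)
        if (it + 1) % trace_every == 0 or it + 1 == n_iter:
            trace.residuals.append(_residual(f, s, geom))
            trace.negatives.append(n_neg)
            trace.iterations.append(it + 1)
    return f.reshape(geom.N, geom.N), trace
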