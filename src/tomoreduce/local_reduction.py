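"""Local measurement reduction: PSF-mask deconvolution of backprojection images.

The unfiltered-backprojection image ``eta`` is modeled as a translation-
invariant blur of the true object: ``eta = b * f + mu`` where ``b`` is the
(2M+1)x(2M+1) point-spread function of acquisition followed by unfiltered
backprojection, and ``mu`` is image-domain noise (treated as white with
standard deviation ``sigma_img``).

A correction mask ``r`` is found so that the windowed convolution of ``r``
with ``b`` is the discrete delta (unbiasedness):

    sum_{i,j} r_{i,j} b_{i-n, j-m} = delta_{0,n} delta_{0,m},   |n|,|m| <= M,

either by solving this linear system exactly or, when it is degenerate or the
noise amplification ``sigma_img^2 sum r^2`` is unacceptable, by ridge
regularization with the multiplier found by scalar root-finding.  Applying the
mask to every pixel of ``eta`` gives a locally optimal linear estimate of the
object; negative pixels are then refined using an exact "dummy measurement"
of zero brightness, which propagates to neighbouring pixels through the known
correlation structure of the masked estimate (its autocorrelation), and the
variance of every touched neighbour never increases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .backprojection import clip_nonnegative, unfiltered_backprojection
from .geometry import ScanGeometry, forward_project, omega_mask
from .linear_reduction import RegularizationControl

__all__ = [
    "PointSpreadFunction",
    "CorrectionMask",
    "LocalResult",
    "estimate_psf",
    "solve_mask",
    "apply_mask",
    "refine_nonnegative",
    "refinement_variance_factors",
    "run_local",
]

logger = logging.getLogger(__name__)


@dataclass
class PointSpreadFunction:
    """Blur kernel ``b`` of acquisition + unfiltered backprojection.

    ``b`` is a (2M+1)x(2M+1) array; array index (M, M) is the kernel origin
    (lag (0, 0)).
    """

    M: int
    b: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        w = 2 * self.M + 1
        if self.b.shape != (w, w):
            raise ValueError(f"PSF shape {self.b.shape} != ({w}, {w})")


@dataclass
class CorrectionMask:
    """Correction mask ``r`` with its normalized autocorrelation.

    ``autocorr[2M + k, 2M + l] = sum_{i,j} r_{i-k, j-l} r_{i,j} / sum r^2``
    for lags ``|k|, |l| <= 2M``; the zero-lag value is exactly 1.
    """

    M: int
    r: np.ndarray
    sigma_img: float = 0.0
    autocorr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        w = 2 * self.M + 1
        if self.r.shape != (w, w):
            raise ValueError(f"mask shape {self.r.shape} != ({w}, {w})")
        if self.autocorr is None:
            full = fftconvolve(self.r, self.r[::-1, ::-1], mode="full")
            full /= float(np.sum(self.r**2))
            full[2 * self.M, 2 * self.M] = 1.0  # exact by construction
            self.autocorr = full

    def autocorr_window(self) -> np.ndarray:
        """Central (2M+1)x(2M+1) block of the autocorrelation (lags <= M)."""
        M = self.M
        return self.autocorr[M : 3 * M + 1, M : 3 * M + 1]


@dataclass
class LocalResult:
    """Output of the local pipeline with its intermediate stages."""

    image: np.ndarray
    linear_estimate: np.ndarray
    eta: np.ndarray
    psf: PointSpreadFunction
    mask: CorrectionMask


def estimate_psf(geom: ScanGeometry, M: int) -> PointSpreadFunction:
    """PSF from a simulated point object at the image centre.

    Simulates a unit point at the central pixel, forward-projects with the
    same sensors and angles as the real acquisition, backprojects without
    filtering and crops the (2M+1)x(2M+1) window around the point.
    """
    N = geom.N
    c = N // 2
    if c - M < 0 or c + M >= N:
        raise ValueError(f"window half-size M={M} exceeds the image (N={N})")
    point = np.zeros((N, N))
    point[c, c] = 1.0
    eta = unfiltered_backprojection(forward_project(point, geom), geom)
    b = eta[c - M : c + M + 1, c - M : c + M + 1].copy()
    return PointSpreadFunction(M=M, b=b)


def _convolution_matrix(psf: PointSpreadFunction) -> np.ndarray:
    """Matrix of the windowed convolution with ``b``: C[(n,m),(i,j)] = b_{n-i, m-j}.

    The unbiasedness system ``C r = delta`` then states that convolving the
    mask with the blur reproduces a point, in the same orientation in which
    the mask is later applied to the observation (out-of-window values of
    ``b`` are taken as zero).
    """
    M = psf.M
    w = 2 * M + 1
    C = np.zeros((w * w, w * w))
    for n in range(-M, M + 1):
        for m in range(-M, M + 1):
            row = (n + M) * w + (m + M)
            for i in range(-M, M + 1):
                for j in range(-M, M + 1):
                    di, dj = n - i, m - j
                    if -M <= di <= M and -M <= dj <= M:
                        C[row, (i + M) * w + (j + M)] = psf.b[di + M, dj + M]
    return C


def mask_residual(psf: PointSpreadFunction, mask: CorrectionMask) -> float:
    """Euclidean norm of the unbiasedness residual ``C r - delta``."""
    C = _convolution_matrix(psf)
    w = 2 * psf.M + 1
    e = np.zeros(w * w)
    e[psf.M * w + psf.M] = 1.0
    return float(np.linalg.norm(C @ mask.r.ravel() - e))


def solve_mask(
    psf: PointSpreadFunction,
    mode: str = "exact",
    ctrl: RegularizationControl | None = None,
    sigma_img: float = 0.0,
) -> CorrectionMask:
    """Solve for the correction mask ``r``.

    mode='exact' solves the unbiasedness system directly and raises if it is
    numerically singular (advising the regularized mode).  mode='regularized'
    minimizes the unbiasedness residual under the noise-amplification budget
    ``sigma_img**2 * sum(r**2) <= ctrl.epsilon`` (Lagrangian ridge, multiplier
    by scalar root-finding), or uses ``ctrl.omega`` as the ridge multiplier
    directly.
    """
    C = _convolution_matrix(psf)
    w = 2 * psf.M + 1
    e = np.zeros(w * w)
    e[psf.M * w + psf.M] = 1.0

    if mode == "exact":
        cond = np.linalg.cond(C)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "unbiasedness system is degenerate; use mode='regularized'"
            )
        r = np.linalg.solve(C, e)
        return CorrectionMask(M=psf.M, r=r.reshape(w, w), sigma_img=sigma_img)

    if mode != "regularized":
        raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'regularized'")
    if ctrl is None:
        raise ValueError("regularized mode needs a RegularizationControl")

    CtC = C.T @ C
    Cte = C.T @ e

    def solve_ridge(mu: float) -> np.ndarray:
        return np.linalg.solve(CtC + mu * np.eye(CtC.shape[0]), Cte)

    if ctrl.omega is not None:
        r = solve_ridge(ctrl.omega)
    else:
        if sigma_img <= 0:
            raise ValueError("epsilon mode needs a positive sigma_img")
        eps = ctrl.epsilon
        r0, *_ = np.linalg.lstsq(C, e, rcond=None)
        if sigma_img**2 * float(np.sum(r0**2)) <= eps:
            r = r0
        else:

            def excess(log_mu: float) -> float:
                rr = solve_ridge(float(np.exp(log_mu)))
                return sigma_img**2 * float(np.sum(rr**2)) - eps

            lo, hi = -30.0, 1.0
            while excess(hi) > 0:
                hi += 5.0
                if hi > 60:
                    raise ValueError("epsilon below the achievable range")
            log_mu = brentq(excess, lo, hi, rtol=1e-8, xtol=1e-12)
            r = solve_ridge(float(np.exp(log_mu)))
    return CorrectionMask(M=psf.M, r=r.reshape(w, w), sigma_img=sigma_img)


def apply_mask(eta: np.ndarray, mask: CorrectionMask) -> np.ndarray:
    """Convolve the observation with the mask (zero-padded boundaries)."""
    eta = np.asarray(eta, dtype=float)
    return fftconvolve(eta, mask.r, mode="same")


def refinement_variance_factors(mask: CorrectionMask) -> np.ndarray:
    """Variance reduction ``D f_hat_hat / D f_hat = 1 - c_{k,l}^2`` per lag.

    One dummy-measurement update of a negative pixel replaces each neighbour's
    variance ``D f_hat = sigma_img^2 sum r^2`` by
    ``D f_hat - cov^2 / D f_hat_00`` with ``cov = sigma_img^2 sum r r_shift``;
    the ratio depends only on the mask autocorrelation, so it is never above 1.
    """
    c = mask.autocorr_window()
    return 1.0 - c**2


def refine_nonnegative(
    f: np.ndarray,
    mask: CorrectionMask,
    max_passes: int = 1,
    tol: float = 1e-12,
) -> np.ndarray:
    """Dummy-measurement non-negativity refinement of a masked estimate.

    Pixels are scanned in raster order; each pixel found below ``-tol`` is
    treated as an exact additional measurement of zero brightness: every
    neighbour within the (2M+1) window moves by ``c_{k,l} * (0 - value)``
    where ``c`` is the mask autocorrelation (the triggering pixel itself lands
    exactly at 0 since ``c_{0,0} = 1``).  The result is clipped non-negative
    at the end.

    The default is a single whole-image sweep.  The update formula is the
    best linear correction for the *original* estimate covariance; reapplying
    it without downdating that covariance over-corrects, and when negative
    pixels are dense (e.g. a negative background) iterating sweeps is an
    expansive map that inflates both signal and negatives instead of
    converging.  ``max_passes > 1`` repeats sweeps until no pixel is below
    ``-tol`` or the cap is reached, which is safe when negatives are sparse.
    """
    f = np.array(f, dtype=float)
    M = mask.M
    c = mask.autocorr_window()
    H, W = f.shape
    for _ in range(max_passes):
        triggered = False
        for p, q in np.argwhere(f < -tol):
            v = f[p, q]
            if v >= -tol:  # may have been fixed by an earlier neighbour update
                continue
            triggered = True
            r0, r1 = max(p - M, 0), min(p + M + 1, H)
            c0, c1 = max(q - M, 0), min(q + M + 1, W)
            f[r0:r1, c0:c1] += (
                c[M - (p - r0) : M + (r1 - p), M - (q - c0) : M + (c1 - q)] * -v
            )
            f[p, q] = 0.0  # exact: c_{0,0} = 1
        if not triggered and not np.any(f < -tol):
            break
    else:
        if np.any(f < -tol):
            logger.info(
                "non-negativity refinement did not converge in %d passes; clipping",
                max_passes,
            )
    return clip_nonnegative(f)


def run_local(
    s: np.ndarray,
    geom: ScanGeometry,
    M: int = 2,
    mode: str = "exact",
    ctrl: RegularizationControl | None = None,
    sigma_img: float | None = None,
    max_passes: int = 1,
) -> LocalResult:
    """Full local pipeline: backproject, estimate PSF, mask, refine.

    ``sigma_img=None`` estimates the image-domain noise level as the standard
    deviation of the backprojection outside the reconstruction disc Omega.
    """
    eta = unfiltered_backprojection(s, geom)
    if sigma_img is None:
        outside = ~omega_mask(geom)
        sigma_img = float(np.std(eta[outside])) if np.any(outside) else 0.0
    psf = estimate_psf(geom, M)
    mask = solve_mask(psf, mode=mode, ctrl=ctrl, sigma_img=sigma_img)
    linear = apply_mask(eta, mask)
    refined = refine_nonnegative(linear, mask, max_passes=max_passes)
    return LocalResult(
        image=refined, linear_estimate=linear, eta=eta, psf=psf, mask=mask
    )
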