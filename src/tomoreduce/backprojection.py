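"""Backprojection baselines: unfiltered, ramp-filtered, and helpers.

Unfiltered backprojection smears every sinogram value back over its strip and
sums; here it is implemented as the *exact transpose* of the forward
projector, so it coincides with :func:`tomoreduce.geometry.adjoint_project`.
(In the continuous theory the adjoint and backprojection differ by a constant
factor of 2*pi; with the exact-transpose convention used throughout this
package the factor is 1.)

The filtered variant convolves each angle's sensor row with the standard
discrete ramp sequence (frequency response |omega|) before backprojecting.
No apodization window is applied.
"""

from __future__ import annotations

import numpy as np

from .geometry import ScanGeometry, adjoint_project, _check_sinogram

__all__ = [
    "unfiltered_backprojection",
    "filtered_backprojection",
    "ramp_filter_rows",
    "fit_scale",
    "clip_nonnegative",
]


def unfiltered_backprojection(s: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Backproject a sinogram without filtering (exact transpose of A)."""
    return adjoint_project(s, geom)


def _ramp_response(n: int) -> np.ndarray:
    """Frequency response of the discrete ramp filter on ``n`` sensors.

    Built as the DFT of the band-limited spatial ramp sequence
    h[0] = 1/4, h[k] = 0 for even k, h[k] = -1/(pi*k)^2 for odd k, wrapped
    circularly, with the DC bin forced to exactly zero (the infinite sequence
    sums to zero; circular truncation leaves a small residual otherwise).
    A constant row therefore filters to an exactly zero row.
    """
    h = np.zeros(n)
    odd = np.arange(1, (n + 1) // 2, 2)
    h[0] = 0.25
    h[odd] = -1.0 / (np.pi * odd) ** 2
    h[n - odd] = -1.0 / (np.pi * odd) ** 2
    resp = np.real(np.fft.fft(h))
    resp[0] = 0.0
    return resp


def ramp_filter_rows(s: np.ndarray) -> np.ndarray:
    """Apply the discrete ramp filter along the sensor axis of a sinogram.

    The filter acts circularly over the sensor axis; the object's support in
    the reconstruction disc keeps its shadow away from the wrap-around.
    """
    s = np.asarray(s, dtype=float)
    J = s.shape[-1]
    resp = _ramp_response(J)
    return np.real(np.fft.ifft(np.fft.fft(s, axis=-1) * resp, axis=-1))


def filtered_backprojection(
    s: np.ndarray, geom: ScanGeometry, filter: str = "ramp"
) -> np.ndarray:
    """Ramp-filtered backprojection; ``filter='none'`` gives the unfiltered one."""
    s = _check_sinogram(s, geom)
    if filter == "none":
        return unfiltered_backprojection(s, geom)
    if filter != "ramp":
        raise ValueError(f"unknown filter {filter!r}; expected 'ramp' or 'none'")
    return adjoint_project(ramp_filter_rows(s), geom)


def fit_scale(image_a: np.ndarray, image_b: np.ndarray, mask=None) -> float:
    """Least-squares scalar c minimizing ||image_a - c*image_b|| over mask."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if mask is not None:
        a = a[mask]
        b = b[mask]
    denom = float(np.dot(b.ravel(), b.ravel()))
    if denom == 0.0:
        raise ValueError("reference image is identically zero on the mask")
    return float(np.dot(a.ravel(), b.ravel())) / denom


def clip_nonnegative(f: np.ndarray) -> np.ndarray:
    """Elementwise maximum with zero."""
    return np.maximum(np.asarray(f, dtype=float), 0.0)
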