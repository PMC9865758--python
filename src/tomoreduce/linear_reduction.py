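"""Optimal and regularized linear measurement reduction (dense, small instances).

Measurement model: ``xi = A f + nu`` with zero-mean noise ``nu`` of known
covariance ``Sigma_nu``; the goal is the output ``U f`` of an ideal transducer
(``U = I`` by default: the pixelized object itself).  The minimax-MSE linear
estimator is

    R* = U (Sigma_nu^{-1/2} A)^- Sigma_nu^{-1/2},

with minimal MSE  ``h(R*) = tr U (A* Sigma_nu^{-1} A)^- U*``  whenever the
reducibility condition ``U (I - A^- A) = 0`` holds (``^-`` is the
Moore-Penrose pseudoinverse).  The regularized family

    R_omega = U A* (A A* + omega Sigma_nu)^{-1}

trades bias for noise suppression; ``omega`` may be given directly or found by
root-finding so that the noise energy ``||R Sigma_nu^{1/2}||_HS^2`` meets a
budget ``epsilon`` (for ``epsilon >= h(R*)`` the unregularized ``R*`` is
already admissible and is returned).

Non-negativity is imposed by the dummy-measurement fixed point: the current
estimate is appended to the real measurement as an extra observation of ``U f``
with covariance ``Sigma_{R* xi}``, reduced, and projected (Euclidean) onto the
non-negative cone; the fixed point of this map is the refined estimate.

Everything here uses dense linear algebra and is intended for instances small
enough to pseudoinvert directly; the local and iterative modules exist
precisely to avoid this path at sinogram scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import brentq

from .geometry import NoiseModel

__all__ = [
    "ReductionProblem",
    "ReductionResult",
    "RegularizationControl",
    "FixedPointResult",
    "optimal_reduction",
    "regularized_reduction",
    "fixed_point_nonneg",
]

_RCOND = 1e-10  # relative singular-value cutoff for pseudoinverses
_SIZE_CAP = 2000  # max rows/cols for the dense path


@dataclass
class ReductionProblem:
    """Dense reduction instance: operator ``A``, ideal transducer ``U``, noise.

    ``U=None`` means the identity (recover the pixelized object itself).
    """

    A: np.ndarray
    noise: NoiseModel
    U: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D array")
        m, n = self.A.shape
        if max(m, n) > _SIZE_CAP:
            raise ValueError(
                f"instance {self.A.shape} too large for dense reduction "
                f"(cap {_SIZE_CAP}); use the local or iterative methods"
            )
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)
            if self.U.shape[1] != n:
                raise ValueError("column counts of A and U must agree")

    @property
    def n_meas(self) -> int:
        return self.A.shape[0]

    @property
    def n_feat(self) -> int:
        return self.A.shape[1]

    def u_matrix(self) -> np.ndarray:
        return np.eye(self.n_feat) if self.U is None else self.U

    def noise_scales(self) -> np.ndarray:
        """Row scales ``Sigma_nu^{-1/2}`` (diagonal noise only)."""
        var = self.noise.variance_vector(self.n_meas)
        if np.any(var <= 0):
            raise ValueError("reduction requires strictly positive noise variances")
        return 1.0 / np.sqrt(var)


@dataclass
class ReductionResult:
    """Optimal reduction operator with its error characterization."""

    R: np.ndarray
    mse: float
    covariance: np.ndarray
    reducibility_defect: float


@dataclass(frozen=True)
class RegularizationControl:
    """Either a noise-energy budget ``epsilon`` or a Lagrange parameter ``omega``."""

    epsilon: float = None  # type: ignore[assignment]
    omega: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.epsilon is None) == (self.omega is None):
            raise ValueError("give exactly one of epsilon or omega")
        val = self.epsilon if self.epsilon is not None else self.omega
        if val <= 0:
            raise ValueError("epsilon / omega must be positive")


@dataclass
class FixedPointResult:
    estimate: np.ndarray
    n_iter: int
    converged: bool
    delta: float
    linear_estimate: np.ndarray = field(default=None)  # type: ignore[assignment]


def optimal_reduction(p: ReductionProblem) -> ReductionResult:
    """Minimax-MSE linear reduction ``R*`` with MSE, covariance and defect."""
    U = p.u_matrix()
    scales = p.noise_scales()
    Aw = p.A * scales[:, None]  # Sigma^{-1/2} A
    Aw_pinv = np.linalg.pinv(Aw, rcond=_RCOND)
    R = U @ (Aw_pinv * scales[None, :])
    gram_pinv = np.linalg.pinv(Aw.T @ Aw, rcond=_RCOND)  # (A* Sigma^-1 A)^-
    cov = U @ gram_pinv @ U.T
    cov = 0.5 * (cov + cov.T)
    A_pinv = np.linalg.pinv(p.A, rcond=_RCOND)
    defect = float(np.linalg.norm(U @ (np.eye(p.n_feat) - A_pinv @ p.A)))
    return ReductionResult(
        R=R,
        mse=float(np.trace(cov)),
        covariance=cov,
        reducibility_defect=defect,
    )


def _reg_operator(p: ReductionProblem, omega: float) -> np.ndarray:
    U = p.u_matrix()
    var = p.noise.variance_vector(p.n_meas)
    G = p.A @ p.A.T + omega * np.diag(var)
    try:
        sol = scipy.linalg.solve(G, p.A, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValueError(f"(AA* + omega Sigma_nu) singular at omega={omega}") from exc
    return U @ sol.T


def _noise_energy(p: ReductionProblem, R: np.ndarray) -> float:
    """Hilbert-Schmidt norm squared ``||R Sigma_nu^{1/2}||^2``."""
    var = p.noise.variance_vector(p.n_meas)
    return float(np.sum(R**2 * var[None, :]))


def regularized_reduction(
    p: ReductionProblem, ctrl: RegularizationControl
) -> np.ndarray:
    """Regularized reduction ``R = U A* (A A* + omega Sigma_nu)^{-1}``.

    With ``ctrl.omega`` the operator is returned directly.  With
    ``ctrl.epsilon`` the Lagrange parameter is found by scalar root-finding so
    that the noise energy equals epsilon (relative tolerance 1e-6); a budget at
    or above the optimal reduction's MSE-level noise energy switches to ``R*``.
    """
    if ctrl.omega is not None:
        return _reg_operator(p, ctrl.omega)

    eps = ctrl.epsilon
    base = optimal_reduction(p)
    e_star = _noise_energy(p, base.R)
    if eps >= e_star:
        return base.R

    def excess(log_omega: float) -> float:
        return _noise_energy(p, _reg_operator(p, np.exp(log_omega))) - eps

    lo, hi = -20.0, 1.0
    while excess(hi) > 0:
        hi += 5.0
        if hi > 60:
            raise ValueError("epsilon below the achievable noise-energy range")
    while excess(lo) < 0:
        lo -= 5.0
        if lo < -80:
            break
    if excess(lo) < 0:
        raise ValueError("epsilon outside the achievable noise-energy range")
    log_omega = brentq(excess, lo, hi, rtol=1e-8, xtol=1e-12)
    return _reg_operator(p, float(np.exp(log_omega)))


def _inv_sqrt_psd(S: np.ndarray) -> np.ndarray:
    """Pseudo inverse square root of a symmetric PSD matrix."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    cut = _RCOND * max(w.max(), 0.0) if w.size else 0.0
    inv_sqrt = np.where(w > cut, 1.0 / np.sqrt(np.clip(w, cut, None)), 0.0)
    return (V * inv_sqrt[None, :]) @ V.T


def fixed_point_nonneg(
    xi: np.ndarray,
    p: ReductionProblem,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> FixedPointResult:
    """Non-negative refinement of the reduction estimate via dummy measurement.

    The iteration treats the stacked vector ``[xi; u_t]`` as a measurement by
    the stacked transducer ``[A; U]`` with block-diagonal noise covariance
    ``diag(Sigma_nu, Sigma_{R* xi})``, reduces it optimally, and projects the
    result onto the non-negative cone.  Starts from ``max(R* xi, 0)``; stops
    when successive iterates differ (Euclidean norm) by less than ``tol``.
    Non-convergence is reported through ``converged=False`` with the last
    iterate.
    """
    xi = np.asarray(xi, dtype=float).ravel()
    if xi.size != p.n_meas:
        raise ValueError(f"measurement size {xi.size} != {p.n_meas}")
    base = optimal_reduction(p)
    U = p.u_matrix()
    n_u = U.shape[0]

    A_stack = np.vstack([p.A, U])
    W = np.zeros((p.n_meas + n_u, p.n_meas + n_u))
    W[: p.n_meas, : p.n_meas] = np.diag(p.noise_scales())
    W[p.n_meas :, p.n_meas :] = _inv_sqrt_psd(base.covariance)
    R_stack = U @ np.linalg.pinv(W @ A_stack, rcond=_RCOND) @ W
    R_xi = R_stack[:, : p.n_meas]
    R_u = R_stack[:, p.n_meas :]

    linear = base.R @ xi
    u = np.maximum(linear, 0.0)
    fixed_part = R_xi @ xi
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        u_next = np.maximum(fixed_part + R_u @ u, 0.0)
        delta = float(np.linalg.norm(u_next - u))
        u = u_next
        if delta < tol:
            break
    return FixedPointResult(
        estimate=u,
        n_iter=it,
        converged=delta < tol,
        delta=delta,
        linear_estimate=linear,
    )
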