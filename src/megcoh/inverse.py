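"""Tikhonov-regularized minimum-norm inverse operators and L-curve selection.

The minimum-norm estimate solves

    Ŝ = argmin_S ‖Q^{-1/2}(M − L·S)‖² + γ·‖R^{-1/2}·S‖²,

whose closed form is the linear operator

    W = R·Lᵀ·(L·R·Lᵀ + γ·Q)⁻¹,        Ŝ = W·M,

with R the source covariance (identity for the classical MNE used here), Q
the noise covariance, and γ the composite Tikhonov regularization weight
(the λ² multiplying Q).  The study's weights are spaced one decade apart.

The L-curve plots the weighted solution norm against the whitened residual
norm over the weight grid (log-log); its corner — the point of maximum
discrete curvature — is the classic data-driven weight selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import (
    CornerUndefinedError,
    ParameterError,
    RankDeficiencyError,
    ShapeError,
)
from .geometry import LeadField
from .simulate import NoiseCovariance

__all__ = [
    "InverseOperator",
    "LCurve",
    "make_inverse_operator",
    "apply_inverse",
    "lambda_grid",
    "lcurve_select",
    "stabilize_covariance",
    "WhitenedSystem",
]

Q_RIDGE_FRACTION = 1e-12  # relative ridge added to Q for numerical safety


@dataclass
class InverseOperator:
    """Regularized minimum-norm operator (sources × channels)."""

    w: np.ndarray
    reg_weight: float
    source_cov: np.ndarray | None  # None encodes the identity R
    noise_cov: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ParameterError("inverse operator contains non-finite entries")
        if self.reg_weight < 0:
            raise ParameterError("reg_weight must be >= 0")


@dataclass
class LCurve:
    """Residual/solution norm trade-off over a regularization grid."""

    grid: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    corner_weight: float
    corner_index: int


def _as_cov(cov, n: int, name: str) -> np.ndarray | None:
    """Normalize a covariance argument: None/scalar/array -> array or None."""
    if cov is None:
        return None
    if isinstance(cov, NoiseCovariance):
        cov = cov.q
    if np.isscalar(cov):
        return float(cov) * np.eye(n)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (n, n):
        raise ShapeError(f"{name} must be {n}×{n}, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ParameterError(f"{name} must be symmetric")
    return cov


def stabilize_covariance(q: np.ndarray, fraction: float = Q_RIDGE_FRACTION) -> np.ndarray:
    """Ridge-stabilize a covariance: Q + fraction·(trace Q / n)·I."""
    n = q.shape[0]
    return q + fraction * (np.trace(q) / n) * np.eye(n)


def make_inverse_operator(
    lf: LeadField | np.ndarray,
    source_cov,
    noise_cov,
    reg_weight: float,
) -> InverseOperator:
    """Build W = R·Lᵀ·(L·R·Lᵀ + γ·Q)⁻¹ via a symmetric linear solve.

    ``source_cov`` / ``noise_cov`` accept None (identity), a scalar (scaled
    identity) or a full matrix.  ``reg_weight = 0`` requires L·R·Lᵀ to be
    invertible and otherwise raises :class:`RankDeficiencyError`.
    """
    gain = lf.gain if isinstance(lf, LeadField) else np.asarray(lf, float)
    n_ch, n_src = gain.shape
    if reg_weight < 0:
        raise ParameterError("reg_weight must be >= 0")
    R = _as_cov(source_cov, n_src, "source covariance")
    Q = _as_cov(noise_cov, n_ch, "noise covariance")
    if Q is None:
        Q = np.eye(n_ch)
    Q = stabilize_covariance(Q)
    LR = gain if R is None else gain @ R
    A = LR @ gain.T + reg_weight * Q
    A = 0.5 * (A + A.T)
    try:
        c, low = scipy.linalg.cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "L·R·Lᵀ + γ·Q is not positive definite; increase the "
            "regularization weight"
        ) from exc
    # W = (A⁻¹·L·R)ᵀ, exploiting symmetry of A and R
    w = scipy.linalg.cho_solve((c, low), LR).T
    if not np.all(np.isfinite(w)):
        raise RankDeficiencyError(
            "solve produced non-finite entries; the unregularized system is "
            "numerically singular — use a positive regularization weight"
        )
    return InverseOperator(w, float(reg_weight), R, Q)


def apply_inverse(op: InverseOperator, sensor_data: np.ndarray) -> np.ndarray:
    """Estimated source activity Ŝ = W·M (sources × time)."""
    sensor_data = np.asarray(sensor_data, float)
    data = sensor_data[:, None] if sensor_data.ndim == 1 else sensor_data
    if data.shape[0] != op.w.shape[1]:
        raise ShapeError(
            f"sensor data has {data.shape[0]} channels, operator expects "
            f"{op.w.shape[1]}"
        )
    est = op.w @ data
    return est[:, 0] if sensor_data.ndim == 1 else est


def lambda_grid(low_exponent: int, high_exponent: int) -> np.ndarray:
    """Decade-spaced regularization weights 10^low … 10^high inclusive."""
    if low_exponent > high_exponent:
        raise ParameterError("low_exponent must not exceed high_exponent")
    return 10.0 ** np.arange(low_exponent, high_exponent + 1)


@dataclass
class WhitenedSystem:
    """SVD of the prewhitened gain, for fast multi-weight solves.

    With Q^{-1/2}·L·R^{1/2} = U·diag(s)·Vᵀ, the minimum-norm filter factors
    at weight γ are s/(s² + γ): the operator in whitened sensor coordinates
    is R^{1/2}·V·diag(s/(s²+γ))·Uᵀ.
    """

    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray
    iq_half: np.ndarray  # Q^{-1/2}

    @classmethod
    def from_gain(cls, gain: np.ndarray, noise_cov, source_cov=None) -> "WhitenedSystem":
        n_ch = gain.shape[0]
        Q = _as_cov(noise_cov, n_ch, "noise covariance")
        if Q is None:
            iq_half = np.eye(n_ch)
        else:
            Q = stabilize_covariance(Q)
            evals, evecs = np.linalg.eigh(Q)
            if evals.min() <= 0:
                raise RankDeficiencyError("noise covariance not positive definite")
            iq_half = (evecs / np.sqrt(evals)) @ evecs.T
        if source_cov is not None:
            R = _as_cov(source_cov, gain.shape[1], "source covariance")
            evals, evecs = np.linalg.eigh(R)
            if evals.min() < -1e-12 * evals.max():
                raise ParameterError("source covariance must be PSD")
            r_half = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
            gain = gain @ r_half
        u, s, vt = np.linalg.svd(iq_half @ gain, full_matrices=False)
        return cls(u, s, vt, iq_half)

    def operator_whitened(self, reg_weight: float) -> np.ndarray:
        """Sources × channels operator acting on *whitened* sensor data."""
        f = self.s / (self.s**2 + reg_weight)
        return (self.vt.T * f) @ self.u.T


def lcurve_select(
    lf: LeadField | np.ndarray,
    source_cov,
    noise_cov,
    sensor_data: np.ndarray,
    grid: np.ndarray,
) -> LCurve:
    """L-curve over a weight grid with circumscribed-circle corner detection.

    For each weight the whitened residual norm ‖Q^{-1/2}(M − L·Ŝ)‖_F and the
    weighted solution norm ‖R^{-1/2}·Ŝ‖_F are computed from the SVD of the
    prewhitened gain; the corner is the interior grid point of maximum
    Menger (three-point circumscribed-circle) curvature of the log-log
    polyline.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise CornerUndefinedError("L-curve needs at least 3 grid points")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing and positive")
    gain = lf.gain if isinstance(lf, LeadField) else np.asarray(lf, float)
    sensor_data = np.atleast_2d(np.asarray(sensor_data, float))
    if sensor_data.shape[0] != gain.shape[0]:
        raise ShapeError("sensor data channel count does not match the gain")
    ws = WhitenedSystem.from_gain(gain, noise_cov, source_cov)
    mw = ws.iq_half @ sensor_data
    coeff = ws.u.T @ mw
    r_i = np.sum(coeff**2, axis=1)  # energy along each whitened singular vector
    out_of_range = max(float(np.sum(mw**2) - r_i.sum()), 0.0)

    residual = np.empty(grid.size)
    solution = np.empty(grid.size)
    for k, g in enumerate(grid):
        shrink = g / (ws.s**2 + g)  # residual filter  γ/(s²+γ)
        filt = ws.s / (ws.s**2 + g)  # solution filter  s/(s²+γ)
        residual[k] = np.sqrt(np.sum(shrink**2 * r_i) + out_of_range)
        solution[k] = np.sqrt(np.sum(filt**2 * r_i))

    x = np.log10(np.maximum(residual, 1e-300))
    y = np.log10(np.maximum(solution, 1e-300))
    curvature = np.zeros(grid.size)
    for k in range(1, grid.size - 1):
        p0 = np.array([x[k - 1], y[k - 1]])
        p1 = np.array([x[k], y[k]])
        p2 = np.array([x[k + 1], y[k + 1]])
        d1, d2 = p1 - p0, p2 - p0
        area2 = abs(d1[0] * d2[1] - d1[1] * d2[0])  # twice the triangle area
        denom = (
            np.linalg.norm(p1 - p0) * np.linalg.norm(p2 - p1) * np.linalg.norm(p2 - p0)
        )
        curvature[k] = 2.0 * area2 / denom if denom > 0 else 0.0
    if np.all(curvature[1:-1] < 1e-12):
        raise CornerUndefinedError(
            "log-log L-curve is collinear over the grid; widen the grid"
        )
    corner = int(np.argmax(curvature[1:-1])) + 1
    return LCurve(grid, residual, solution, float(grid[corner]), corner)
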