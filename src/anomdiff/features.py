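"""Trajectory statistics: TAMSD, anomalous exponent and auxiliary features.

The time-averaged mean squared displacement (TAMSD) of a trajectory sampled at
``r_1, ..., r_N`` is, at lag ``n`` frames,

    tamsd(n) = 1/(N-n) * sum_{i=1}^{N-n} |r_{i+n} - r_i|^2 ,

and the classical analysis fits ``tamsd(Delta) ~ K_alpha * Delta^alpha`` on a
log-log scale; the anomalous exponent ``alpha`` separates subdiffusion
(alpha < 1), normal diffusion (alpha = 1) and superdiffusion (alpha > 1).

The auxiliary scalar features follow the standard definitions from the
feature-based SPT classification literature:

* asymmetry ``a = -ln(1 - (l1 - l2)^2 / (2 (l1 + l2)^2))`` from the gyration
  tensor eigenvalues ``l1 >= l2``;
* efficiency ``E = |r_N - r_1|^2 / ((N-1) * sum_i |r_{i+1} - r_i|^2)``;
* fractal dimension via Katz's estimator
  ``D_f = log(n) / (log(n) + log(d/L))`` with ``n`` the step count, ``d`` the
  path diameter and ``L`` the total path length;
* TAMSD at lag 20 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulate import Trajectory

__all__ = [
    "TamsdCurve",
    "PowerLawFit",
    "TheoreticalMsdParams",
    "FeatureVector",
    "tamsd",
    "tamsd_curve",
    "fit_power_law",
    "fit_anomalous_exponent",
    "theoretical_msd",
    "compute_features",
    "increment_autocorrelation",
]


@dataclass(frozen=True)
class TamsdCurve:
    lags: np.ndarray  # seconds, strictly increasing multiples of dt
    values: np.ndarray  # um^2


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of ``tamsd(Delta) = K_alpha * Delta^alpha``."""

    K_alpha: float  # um^2 / s^alpha
    alpha: float


@dataclass(frozen=True)
class TheoreticalMsdParams:
    """Parameters of the closed-form 2-D MSD curves.

    ND:  4*D*Delta
    FBM: 4*D*Delta^alpha
    DM:  4*D*Delta + (v*Delta)^2
    CD:  rc^2 * (1 - A1*exp(-4*A2*D*Delta/rc^2))

    ``A1`` and ``A2`` are dimensionless shape constants of the confinement
    (both default to 1).
    """

    kind: str
    D: float
    v: Optional[float] = None
    rc: Optional[float] = None
    alpha: Optional[float] = None
    A1: float = 1.0
    A2: float = 1.0

    def __post_init__(self) -> None:
        if self.A1 <= 0 or self.A2 <= 0:
            raise ValueError("A1 and A2 must be positive")


@dataclass(frozen=True)
class FeatureVector:
    asymmetry: float
    efficiency: float
    fractal_dimension: float
    tamsd_lag20: float  # um^2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.asymmetry, self.efficiency, self.fractal_dimension, self.tamsd_lag20]
        )


FEATURE_NAMES = ("asymmetry", "efficiency", "fractal_dimension", "tamsd_lag20")


def tamsd(traj: Trajectory, lag: int) -> float:
    """TAMSD at an integer frame lag, in um^2."""
    if not 1 <= lag < traj.n_points:
        raise ValueError(f"lag must lie in [1, {traj.n_points - 1}], got {lag}")
    dx = traj.xs[lag:] - traj.xs[:-lag]
    dy = traj.ys[lag:] - traj.ys[:-lag]
    return float(np.mean(dx * dx + dy * dy))


def tamsd_curve(traj: Trajectory, max_lag: int) -> TamsdCurve:
    """TAMSD evaluated at frame lags 1..max_lag."""
    if not 1 <= max_lag < traj.n_points:
        raise ValueError("max_lag must be in [1, n_points - 1]")
    lags = np.arange(1, max_lag + 1)
    values = np.array([tamsd(traj, int(n)) for n in lags])
    return TamsdCurve(lags=lags * traj.dt, values=values)


def fit_power_law(lags: np.ndarray, values: np.ndarray) -> PowerLawFit:
    """Least-squares line fit of ``log(values)`` vs ``log(lags)``.

    The slope is the anomalous exponent ``alpha``; the intercept gives the
    generalized diffusion coefficient ``K_alpha``.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(lags) < 2:
        raise ValueError("need at least two lags for a line fit")
    if np.any(values <= 0):
        raise ValueError("degenerate trajectory: zero TAMSD at a fitted lag")
    slope, intercept = np.polyfit(np.log(lags), np.log(values), 1)
    return PowerLawFit(K_alpha=float(np.exp(intercept)), alpha=float(slope))


def fit_anomalous_exponent(traj: Trajectory, max_lag: int) -> PowerLawFit:
    """Power-law fit of the TAMSD over frame lags ``1..max_lag``."""
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2 for a line fit")
    curve = tamsd_curve(traj, max_lag)
    return fit_power_law(curve.lags, curve.values)


def theoretical_msd(params: TheoreticalMsdParams, lag: float) -> float:
    """Closed-form ensemble MSD at time lag ``lag`` (seconds), in um^2."""
    if lag <= 0:
        raise ValueError("lag must be positive")
    if params.kind == "ND":
        return 4.0 * params.D * lag
    if params.kind == "FBM":
        if params.alpha is None:
            raise ValueError("FBM curve needs alpha")
        return 4.0 * params.D * lag**params.alpha
    if params.kind == "DM":
        if params.v is None:
            raise ValueError("DM curve needs v")
        return 4.0 * params.D * lag + (params.v * lag) ** 2
    if params.kind == "CD":
        if params.rc is None:
            raise ValueError("CD curve needs rc")
        rc2 = params.rc**2
        return rc2 * (1.0 - params.A1 * math.exp(-4.0 * params.A2 * params.D * lag / rc2))
    raise ValueError(f"unknown diffusion kind {params.kind!r}")


def _gyration_eigenvalues(pos: np.ndarray) -> np.ndarray:
    centered = pos - pos.mean(axis=0)
    tensor = centered.T @ centered / len(pos)
    eig = np.linalg.eigvalsh(tensor)
    return eig[::-1]  # descending


def asymmetry(traj: Trajectory) -> float:
    """Gyration-tensor asymmetry; 0 for point-symmetric paths, large for
    elongated ones (a straight line gives ``ln 2``)."""
    l1, l2 = _gyration_eigenvalues(traj.positions)
    denom = 2.0 * (l1 + l2) ** 2
    if denom == 0:
        raise ValueError("degenerate trajectory: all positions identical")
    ratio = (l1 - l2) ** 2 / denom
    return float(-math.log1p(-ratio))


def efficiency(traj: Trajectory) -> float:
    """Net-displacement share of the summed squared step lengths, in [0, 1]."""
    pos = traj.positions
    steps = np.diff(pos, axis=0)
    denom = (len(pos) - 1) * float(np.sum(steps**2))
    if denom == 0:
        raise ValueError("degenerate trajectory: all positions identical")
    net = pos[-1] - pos[0]
    return float(net @ net / denom)


def fractal_dimension(traj: Trajectory) -> float:
    """Katz's planar-curve fractal dimension; 1 for a straight line."""
    pos = traj.positions
    steps = np.diff(pos, axis=0)
    L = float(np.sum(np.sqrt(np.sum(steps**2, axis=1))))
    if L == 0:
        raise ValueError("degenerate trajectory: zero path length")
    rel = pos - pos[0]
    d = float(np.sqrt(np.max(np.sum(rel**2, axis=1))))
    n = len(pos) - 1  # step count
    return float(math.log(n) / (math.log(n) + math.log(d / L)))


def compute_features(traj: Trajectory) -> FeatureVector:
    """The four auxiliary scalar features of a trajectory."""
    if traj.n_points <= 20:
        raise ValueError("trajectory must have more than 20 points")
    return FeatureVector(
        asymmetry=asymmetry(traj),
        efficiency=efficiency(traj),
        fractal_dimension=fractal_dimension(traj),
        tamsd_lag20=tamsd(traj, 20),
    )


def increment_autocorrelation(traj: Trajectory, lag: int) -> float:
    """Normalized autocorrelation of the step series at an integer lag.

    Computed per coordinate on the increments (positions themselves are
    non-stationary) and averaged over x and y.  Lag 0 returns 1 by
    normalization; anti-correlated increments (subdiffusive FBM) give
    negative values.
    """
    n_incr = traj.n_points - 1
    if not 0 <= lag < n_incr:
        raise ValueError(f"lag must lie in [0, {n_incr - 1}]")
    acfs = []
    for series in (np.diff(traj.xs), np.diff(traj.ys)):
        centered = series - series.mean()
        var = float(centered @ centered)
        if var == 0:
            raise ValueError("constant trajectory: increment variance is zero")
        if lag == 0:
            acfs.append(1.0)
        else:
            acfs.append(float(centered[:-lag] @ centered[lag:]) / var)
    return float(np.mean(acfs))
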