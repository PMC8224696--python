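"""Stochastic simulators for the four diffusion modes.

Single-particle-tracking (SPT) experiments record 2-D particle positions at a
fixed frame interval.  Four generative models cover the phenomenology commonly
seen in such data:

* **ND** — normal (Brownian) diffusion: isotropic steps whose length follows a
  Rayleigh distribution with second moment ``4*D*dt``.
* **DM** — directed motion: Brownian steps superposed with a constant drift of
  speed ``v`` in a direction ``beta`` fixed per trajectory.  Instead of ``v``
  itself, the dimensionless active-motion-to-diffusion ratio
  ``R = v**2 * T / (4 * D)`` is sampled and inverted.
* **CD** — confined diffusion inside a reflecting circular boundary of radius
  ``r_c``; controlled through the boundedness ``B ≈ D*N*dt / r_c**2`` which
  compares the area a free walk would explore with the confinement area.
* **FBM** — subdiffusive fractional Brownian motion with Hurst exponent
  ``H = alpha / 2 ∈ (0, 1/2)``, sampled exactly from its covariance.

All trajectories start at the origin, contain exactly ``N`` positions at times
``i*dt`` and carry coordinates in micrometres.  Localization error is modelled
as i.i.d. Gaussian noise added to every recorded position, parameterized by a
signal-to-noise ratio ``Q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "CLASSES",
    "Trajectory",
    "ModelParams",
    "SimulationConfig",
    "sample_model_params",
    "simulate_nd",
    "simulate_dm",
    "simulate_cd",
    "simulate_fbm",
    "simulate",
    "drift_speed_from_ratio",
    "confinement_radius_from_boundedness",
    "noise_sigma_from_snr",
    "add_noise",
    "child_rng",
]

#: Canonical class order used everywhere (labels, one-hot targets, confusion
#: matrices).
CLASSES: Tuple[str, ...] = ("FBM", "CD", "DM", "ND")

#: Number of sub-steps a confined-diffusion step is divided into.
CD_SUBSTEPS = 100


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled 2-D path.

    Attributes
    ----------
    times : ndarray, seconds, ``times[i] = i * dt``
    xs, ys : ndarray, micrometres
    """

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        t, x, y = (np.asarray(a, dtype=float) for a in (self.times, self.xs, self.ys))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xs", x)
        object.__setattr__(self, "ys", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("times, xs and ys must have equal length")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def positions(self) -> np.ndarray:
        """(n_points, 2) array of coordinates."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class ModelParams:
    """Per-trajectory generative parameters.

    Only the fields relevant for ``kind`` are set; the rest stay ``None``.
    Derived quantities (``v``, ``rc``, ``sigma_noise``) are computed from the
    sampled ratio parameters ``R``, ``B`` and ``Q``.
    """

    kind: str
    D: float  # diffusion coefficient, um^2/s
    N: int  # number of recorded positions
    dt: float  # frame interval, s
    v: Optional[float] = None  # drift speed, um/s (DM)
    beta: Optional[float] = None  # drift direction, rad (DM)
    R: Optional[float] = None  # active-motion-to-diffusion ratio (DM)
    rc: Optional[float] = None  # confinement radius, um (CD)
    B: Optional[float] = None  # boundedness (CD)
    H: Optional[float] = None  # Hurst exponent (FBM)
    alpha: Optional[float] = None  # anomalous exponent = 2H (FBM)
    Q: Optional[float] = None  # signal-to-noise ratio
    sigma_noise: Optional[float] = None  # localization noise std, um

    def __post_init__(self) -> None:
        if self.kind not in CLASSES:
            raise ValueError(f"unknown diffusion class {self.kind!r}; allowed: {CLASSES}")
        if self.D <= 0 or self.dt <= 0 or self.N <= 0:
            raise ValueError("D, dt and N must be strictly positive")
        if self.kind == "FBM":
            if self.H is None or self.alpha is None:
                raise ValueError("FBM requires H and alpha")
            if not 0.0 < self.H < 1.0:
                raise ValueError("H must lie in (0, 1)")
            if not math.isclose(self.alpha, 2.0 * self.H, rel_tol=1e-9):
                raise ValueError("alpha must equal 2*H")

    @property
    def T(self) -> float:
        """Trajectory duration N*dt in seconds."""
        return self.N * self.dt


def _interval(lo: float, hi: float, name: str) -> Tuple[float, float]:
    if lo > hi:
        raise ValueError(f"range_{name}: lower bound exceeds upper bound")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameter ranges of the synthetic corpus.

    Defaults correspond to the study conditions: frame interval 1/30 s,
    diffusion coefficients 0.1-20 um^2/s, trajectory lengths 30-600 frames,
    boundedness 1-6, active-motion ratio 1-17, anomalous exponent 0.3-0.7 and
    signal-to-noise ratio 1-9, each drawn uniformly.
    """

    dt: float = 1.0 / 30.0
    range_D: Tuple[float, float] = (0.1, 20.0)
    range_N: Tuple[int, int] = (30, 600)
    range_B: Tuple[float, float] = (1.0, 6.0)
    range_R: Tuple[float, float] = (1.0, 17.0)
    range_alpha: Tuple[float, float] = (0.3, 0.7)
    range_Q: Tuple[float, float] = (1.0, 9.0)
    n_per_class: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D", "N", "B", "R", "alpha", "Q"):
            lo, hi = getattr(self, f"range_{name}")
            if lo > hi:
                raise ValueError(f"range_{name}: lower bound exceeds upper bound")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def child_rng(seed: int, index: int) -> np.random.Generator:
    """Child random generator for item ``index`` under root ``seed``.

    Uses numpy's SeedSequence spawning so per-trajectory streams are
    independent and reproducible regardless of generation order.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


# ---------------------------------------------------------------------------
# derived-parameter formulas
# ---------------------------------------------------------------------------

def drift_speed_from_ratio(R: float, D: float, T: float) -> float:
    """Drift speed ``v = sqrt(4*D*R/T)`` from the active-motion ratio."""
    if R < 0:
        raise ValueError("R must be non-negative")
    if D <= 0 or T <= 0:
        raise ValueError("D and T must be positive")
    return math.sqrt(4.0 * D * R / T)


def confinement_radius_from_boundedness(B: float, D: float, N: int, dt: float) -> float:
    """Confinement radius ``r_c = sqrt(D*N*dt/B)`` from the boundedness."""
    if B <= 0:
        raise ValueError("B must be positive")
    if D <= 0 or N <= 0 or dt <= 0:
        raise ValueError("D, N and dt must be positive")
    return math.sqrt(D * N * dt / B)


def noise_sigma_from_snr(Q: float, params: ModelParams) -> float:
    """Localization-noise standard deviation implied by the SNR ``Q``.

    ``sigma = sqrt(D*dt)/Q`` for ND, CD and FBM; for DM the drift adds to the
    one-step signal: ``sigma = sqrt(D*dt + (v*dt)**2)/Q``.
    """
    if Q <= 0:
        raise ValueError("Q must be positive")
    if params.kind == "DM":
        if params.v is None:
            raise ValueError("DM params need v to derive the noise level")
        signal = math.sqrt(params.D * params.dt + (params.v * params.dt) ** 2)
    else:
        signal = math.sqrt(params.D * params.dt)
    return signal / Q


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def sample_model_params(
    kind: str, config: SimulationConfig, rng: np.random.Generator
) -> ModelParams:
    """Draw one trajectory's generative parameters for class ``kind``.

    Continuous parameters are uniform over their configured ranges, the
    length ``N`` uniform over integers.  Derived fields (``v``, ``rc``,
    ``sigma_noise``) are computed from the drawn ratios.
    """
    if kind not in CLASSES:
        raise ValueError(f"unknown diffusion class {kind!r}; allowed: {CLASSES}")
    D = float(rng.uniform(*config.range_D))
    N = int(rng.integers(config.range_N[0], config.range_N[1] + 1))
    Q = float(rng.uniform(*config.range_Q))
    dt = config.dt
    extra: dict = {}
    if kind == "DM":
        R = float(rng.uniform(*config.range_R))
        v = drift_speed_from_ratio(R, D, N * dt)
        beta = float(rng.uniform(0.0, 2.0 * math.pi))
        extra = dict(R=R, v=v, beta=beta)
    elif kind == "CD":
        B = float(rng.uniform(*config.range_B))
        rc = confinement_radius_from_boundedness(B, D, N, dt)
        extra = dict(B=B, rc=rc)
    elif kind == "FBM":
        alpha = float(rng.uniform(*config.range_alpha))
        extra = dict(alpha=alpha, H=alpha / 2.0)
    params = ModelParams(kind=kind, D=D, N=N, dt=dt, Q=Q, **extra)
    return replace(params, sigma_noise=noise_sigma_from_snr(Q, params))


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _rayleigh_steps(D: float, dt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Step lengths via inverse-CDF: ``u = sqrt(-4*D*dt*ln(1-U))``.

    The Rayleigh density ``P(u) = (2u / 4Ddt) exp(-u^2 / 4Ddt)`` has second
    moment ``E[u^2] = 4*D*dt``, matching the 2-D Brownian MSD per frame.
    """
    U = rng.random(n)
    return np.sqrt(-4.0 * D * dt * np.log1p(-U))


def _nd_displacements(D: float, dt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    u = _rayleigh_steps(D, dt, n, rng)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([u * np.cos(phi), u * np.sin(phi)])


def _times(N: int, dt: float) -> np.ndarray:
    return np.arange(N, dtype=float) * dt


def simulate_nd(params: ModelParams, rng: np.random.Generator) -> Trajectory:
    """Normal diffusion: isotropic Rayleigh steps accumulated from the origin."""
    if params.kind != "ND":
        raise ValueError("params.kind must be 'ND'")
    steps = _nd_displacements(params.D, params.dt, params.N - 1, rng)
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(_times(params.N, params.dt), pos[:, 0], pos[:, 1])


def simulate_dm(params: ModelParams, rng: np.random.Generator) -> Trajectory:
    """Directed motion: Brownian steps plus a constant per-step drift.

    The drift direction ``beta`` is fixed for the whole trajectory; if not
    already present in ``params`` it is drawn uniformly on [0, 2*pi).
    """
    if params.kind != "DM":
        raise ValueError("params.kind must be 'DM'")
    if params.v is None:
        raise ValueError("DM simulation requires the drift speed v")
    beta = params.beta if params.beta is not None else float(rng.uniform(0.0, 2.0 * math.pi))
    steps = _nd_displacements(params.D, params.dt, params.N - 1, rng)
    drift = params.v * params.dt * np.array([math.cos(beta), math.sin(beta)])
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps + drift, axis=0)])
    return Trajectory(_times(params.N, params.dt), pos[:, 0], pos[:, 1])


def _cd_walk_py(moves: np.ndarray, rc2: float, n_record: int, substeps: int) -> np.ndarray:
    out = np.zeros((n_record, 2))
    x = 0.0
    y = 0.0
    k = 0
    for i in range(1, n_record):
        for _ in range(substeps):
            cx = x + moves[k, 0]
            cy = y + moves[k, 1]
            k += 1
            if cx * cx + cy * cy < rc2:
                x = cx
                y = cy
        out[i, 0] = x
        out[i, 1] = y
    return out


try:  # JIT the sequential rejection walk; identical arithmetic either way
    from numba import njit

    _cd_walk = njit(cache=True)(_cd_walk_py)
except ImportError:  # pragma: no cover
    _cd_walk = _cd_walk_py


def simulate_cd(params: ModelParams, rng: np.random.Generator) -> Trajectory:
    """Confined diffusion inside a reflecting circle of radius ``rc``.

    Every frame is split into ``CD_SUBSTEPS`` normal-diffusion sub-moves at
    ``dt' = dt/100``; a sub-move is accepted only if the proposed position
    stays strictly inside the circle centred on the start position, otherwise
    the particle keeps its place for that sub-step.  Only the per-frame
    positions are recorded.
    """
    if params.kind != "CD":
        raise ValueError("params.kind must be 'CD'")
    if params.rc is None or params.rc <= 0:
        raise ValueError("CD simulation requires a positive confinement radius rc")
    n_sub = (params.N - 1) * CD_SUBSTEPS
    moves = _nd_displacements(params.D, params.dt / CD_SUBSTEPS, n_sub, rng)
    out = _cd_walk(moves, params.rc**2, params.N, CD_SUBSTEPS)
    return Trajectory(_times(params.N, params.dt), out[:, 0], out[:, 1])


def _fgn_exact(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise of length ``n`` with unit time step.

    Davies-Harte circulant embedding; falls back to a Cholesky factorization
    of the increment covariance if the embedding is not non-negative
    definite.  Increment autocovariance:
    ``gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})``.
    """
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    # circulant first row: gamma_0..gamma_n, gamma_{n-1}..gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) >= -1e-12:
        eig = np.clip(eig, 0.0, None)
        m = len(row)
        # Hermitian Gaussian spectrum -> real stationary series
        z = rng.standard_normal(m)
        half = m // 2
        w = np.empty(half + 1, dtype=complex)
        w[0] = z[0] * math.sqrt(m)
        w[half] = z[half] * math.sqrt(m)
        re = z[1:half]
        im = z[half + 1 :]
        w[1:half] = (re + 1j * im) * math.sqrt(m / 2.0)
        series = np.fft.irfft(w * np.sqrt(eig), n=m)
        return series[:n]
    # exact fallback for the rare indefinite embeddings
    idx = np.arange(n)
    cov = 0.5 * (
        (np.abs(idx[:, None] - idx[None, :]) + 1) ** (2 * H)
        - 2 * np.abs(idx[:, None] - idx[None, :]) ** (2 * H)
        + np.abs(np.abs(idx[:, None] - idx[None, :]) - 1) ** (2 * H)
    )
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def fbm_path(H: float, n_steps: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``B_H`` at times ``0, dt, ..., n_steps*dt`` (length n_steps+1).

    Self-similarity rescales the unit-step increments by ``dt**H`` so the
    exact covariance ``0.5*(t^{2H} + s^{2H} - |t-s|^{2H})`` holds at the
    sample times.
    """
    incr = _fgn_exact(H, n_steps, rng) * dt**H
    return np.concatenate([[0.0], np.cumsum(incr)])


def simulate_fbm(
    params: ModelParams, rng: np.random.Generator, allow_super: bool = False
) -> Trajectory:
    """Subdiffusive FBM: independent exact FBM paths in x and y.

    Each coordinate is ``sqrt(2*D) * B_H(t)`` so the 2-D ensemble MSD is
    ``4*D*t^{2H} = 4*D*t^alpha``.
    """
    if params.kind != "FBM":
        raise ValueError("params.kind must be 'FBM'")
    H = params.H
    if H is None or not 0.0 < H < 1.0:
        raise ValueError("H must lie in (0, 1)")
    if H >= 0.5 and not allow_super:
        raise ValueError(
            "H >= 1/2 models super- or normal diffusion; this generator is "
            "restricted to subdiffusive FBM (pass allow_super=True to override)"
        )
    scale = math.sqrt(2.0 * params.D)
    xs = scale * fbm_path(H, params.N - 1, params.dt, rng)
    ys = scale * fbm_path(H, params.N - 1, params.dt, rng)
    return Trajectory(_times(params.N, params.dt), xs, ys)


_SIMULATORS = {
    "ND": simulate_nd,
    "DM": simulate_dm,
    "CD": simulate_cd,
    "FBM": simulate_fbm,
}


def simulate(params: ModelParams, rng: np.random.Generator) -> Trajectory:
    """Dispatch to the simulator matching ``params.kind`` (noiseless)."""
    return _SIMULATORS[params.kind](params, rng)


def add_noise(traj: Trajectory, sigma: float, rng: np.random.Generator) -> Trajectory:
    """Add i.i.d. N(0, sigma^2) localization noise to every coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return traj
    noise = rng.standard_normal((traj.n_points, 2)) * sigma
    return Trajectory(traj.times, traj.xs + noise[:, 0], traj.ys + noise[:, 1])
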