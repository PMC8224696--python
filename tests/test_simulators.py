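"""Unit and statistical tests of the four diffusion-mode simulators."""

import math

import numpy as np
import pytest
from scipy import stats

from anomdiff.simulate import (
    CLASSES,
    ModelParams,
    SimulationConfig,
    add_noise,
    child_rng,
    confinement_radius_from_boundedness,
    drift_speed_from_ratio,
    noise_sigma_from_snr,
    sample_model_params,
    simulate,
    simulate_cd,
    simulate_dm,
    simulate_fbm,
    simulate_nd,
)
from anomdiff.features import tamsd


def _nd_params(D=1.0, N=1000, dt=1.0 / 30.0, **kw):
    return ModelParams(kind="ND", D=D, N=N, dt=dt, **kw)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kind", CLASSES)
def test_sampled_params_respect_ranges_and_derivations(kind, rng):
    config = SimulationConfig()
    for _ in range(100):
        p = sample_model_params(kind, config, rng)
        assert 0.1 <= p.D <= 20.0
        assert 30 <= p.N <= 600
        assert p.dt == pytest.approx(1.0 / 30.0)
        assert 1.0 <= p.Q <= 9.0
        assert p.sigma_noise == pytest.approx(noise_sigma_from_snr(p.Q, p))
        if kind == "DM":
            assert 1.0 <= p.R <= 17.0
            assert p.v == pytest.approx(drift_speed_from_ratio(p.R, p.D, p.T))
            assert 0.0 <= p.beta < 2 * math.pi
            assert p.rc is None and p.H is None
        elif kind == "CD":
            assert 1.0 <= p.B <= 6.0
            assert p.rc == pytest.approx(
                confinement_radius_from_boundedness(p.B, p.D, p.N, p.dt)
            )
            assert p.v is None and p.H is None
        elif kind == "FBM":
            # H = alpha/2 maps the 0.3-0.7 exponent range onto (0.15, 0.35)
            assert 0.15 <= p.H <= 0.35
            assert p.alpha == pytest.approx(2 * p.H)
        else:
            assert p.v is None and p.rc is None and p.H is None


def test_degenerate_ranges_are_deterministic(rng):
    config = SimulationConfig(
        range_D=(1, 1), range_N=(50, 50), range_B=(1, 1), range_R=(1, 1),
        range_alpha=(0.5, 0.5), range_Q=(2, 2),
    )
    p = sample_model_params("ND", config, rng)
    assert p.D == 1.0 and p.N == 50 and p.Q == 2.0


def test_unknown_class_error_names_allowed_classes(rng):
    with pytest.raises(ValueError, match="FBM"):
        sample_model_params("LEVY", SimulationConfig(), rng)


# ---------------------------------------------------------------------------
# normal diffusion
# ---------------------------------------------------------------------------


def test_rayleigh_step_second_moment_matches_4Ddt(rng):
    """E[u^2] = 4*D*dt for the Rayleigh step length (within 3 SE)."""
    D, dt, n = 1.0, 1.0 / 30.0, 100_000
    traj = simulate_nd(_nd_params(D=D, N=n + 1, dt=dt), rng)
    u2 = np.diff(traj.xs) ** 2 + np.diff(traj.ys) ** 2
    expected = 4 * D * dt
    se = expected / math.sqrt(n)  # Var(u^2) = (E[u^2])^2 for Rayleigh
    assert abs(u2.mean() - expected) < 3 * se


def test_step_headings_are_uniform(rng):
    traj = simulate_nd(_nd_params(N=100_001), rng)
    phi = np.arctan2(np.diff(traj.ys), np.diff(traj.xs)) + math.pi
    assert stats.kstest(phi / (2 * math.pi), "uniform").pvalue > 0.01


def test_vanishing_diffusion_freezes_the_particle(rng):
    traj = simulate_nd(_nd_params(D=1e-300, N=100), rng)
    assert np.allclose(traj.xs, 0) and np.allclose(traj.ys, 0)


def test_trajectory_shape_contract(rng):
    traj = simulate_nd(_nd_params(N=50), rng)
    assert traj.n_points == 50
    assert traj.xs[0] == 0 and traj.ys[0] == 0
    assert np.allclose(np.diff(traj.times), 1.0 / 30.0)


# ---------------------------------------------------------------------------
# directed motion
# ---------------------------------------------------------------------------


def test_drift_speed_formula_and_roundtrip():
    assert drift_speed_from_ratio(0.0, 1.0, 5.0) == 0.0
    assert drift_speed_from_ratio(1.0, 1.0, 10.0) == pytest.approx(0.6325, abs=1e-4)
    for R in range(1, 18):
        v = drift_speed_from_ratio(R, 2.5, 7.0)
        assert v**2 * 7.0 / (4 * 2.5) == pytest.approx(R)
    with pytest.raises(ValueError):
        drift_speed_from_ratio(-1.0, 1.0, 1.0)


def test_dm_net_displacement_tracks_drift(rng):
    D, v, N, dt = 0.01, 1.0, 300, 1.0 / 30.0
    p = ModelParams(kind="DM", D=D, N=N, dt=dt, v=v, beta=0.0)
    traj = simulate_dm(p, rng)
    # drift is deterministic; diffusion contributes zero-mean noise with
    # per-axis variance 2*D*T
    sd = math.sqrt(2 * D * (N - 1) * dt)
    assert abs(traj.xs[-1] - v * N * dt) < 3 * sd + v * dt
    assert abs(traj.ys[-1]) < 4 * sd


def test_dm_with_zero_drift_equals_nd_stream():
    p_dm = ModelParams(kind="DM", D=1.0, N=200, dt=1 / 30, v=0.0, beta=0.3)
    p_nd = _nd_params(N=200)
    t_dm = simulate_dm(p_dm, np.random.default_rng(5))
    t_nd = simulate_nd(p_nd, np.random.default_rng(5))
    assert np.allclose(t_dm.xs, t_nd.xs) and np.allclose(t_dm.ys, t_nd.ys)


def test_dm_requires_drift_speed(rng):
    with pytest.raises(ValueError, match="drift speed"):
        simulate_dm(ModelParams(kind="DM", D=1.0, N=10, dt=0.1), rng)


# ---------------------------------------------------------------------------
# confined diffusion
# ---------------------------------------------------------------------------


def test_confinement_radius_formula():
    assert confinement_radius_from_boundedness(1.0, 1.0, 300, 1 / 30) == pytest.approx(
        3.1623, abs=1e-4
    )
    r1 = confinement_radius_from_boundedness(2.0, 1.0, 300, 1 / 30)
    r2 = confinement_radius_from_boundedness(4.0, 1.0, 300, 1 / 30)
    assert r1**2 / r2**2 == pytest.approx(2.0)
    with pytest.raises(ValueError):
        confinement_radius_from_boundedness(0.0, 1.0, 300, 1 / 30)


def test_cd_positions_stay_inside_the_circle(rng):
    for _ in range(5):
        p = sample_model_params("CD", SimulationConfig(range_N=(30, 120)), rng)
        traj = simulate_cd(p, rng)
        r = np.sqrt(traj.xs**2 + traj.ys**2)
        assert np.all(r <= p.rc)
        assert tamsd(traj, traj.n_points - 1) <= 4 * p.rc**2


def test_cd_plateau_grows_with_weaker_confinement(rng):
    """Lower boundedness -> larger confinement circle -> higher TAMSD plateau."""
    D, N, dt = 1.0, 100, 1 / 30
    means = {}
    for B in (1.0, 6.0):
        rc = confinement_radius_from_boundedness(B, D, N, dt)
        vals = []
        for _ in range(200):
            p = ModelParams(kind="CD", D=D, N=N, dt=dt, B=B, rc=rc)
            vals.append(tamsd(simulate_cd(p, rng), 50))
        means[B] = np.mean(vals)
    assert means[1.0] > means[6.0]


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------


def fbm_covariance(t: float, s: float, H: float) -> float:
    """Exact FBM covariance: (|t|^2H + |s|^2H - |t-s|^2H) / 2."""
    return 0.5 * (abs(t) ** (2 * H) + abs(s) ** (2 * H) - abs(t - s) ** (2 * H))


def test_fbm_sample_covariance_matches_analytic(rng):
    H, dt, n = 0.25, 1 / 30, 29
    # x and y are independent exact FBM paths; with sqrt(2D) = 1 both are
    # raw B_H samples, so 2000 trajectories yield 4000 paths
    paths = []
    for _ in range(2000):
        t = simulate_fbm(
            ModelParams(kind="FBM", D=0.5, N=n + 1, dt=dt, H=H, alpha=2 * H), rng
        )
        paths.append(t.xs)
        paths.append(t.ys)
    paths = np.array(paths)
    for i, j in [(5, 5), (10, 10), (15, 15), (25, 25), (14, 16)]:
        emp = float(np.mean(paths[:, i] * paths[:, j]))
        exact = fbm_covariance(i * dt, j * dt, H)
        assert abs(emp - exact) / exact < 0.05


def test_fbm_brownian_limit_has_uncorrelated_increments(rng):
    p = ModelParams(kind="FBM", D=0.5, N=20_001, dt=1.0, H=0.5, alpha=1.0)
    traj = simulate_fbm(p, rng, allow_super=True)
    incr = np.diff(traj.xs)
    for lag in (1, 5, 10):
        rho = np.corrcoef(incr[:-lag], incr[lag:])[0, 1]
        assert abs(rho) < 0.03


def test_fbm_ensemble_msd_follows_power_law(rng):
    H, D, dt = 0.2, 1.0, 1 / 30
    lag_steps = 10
    disp2 = []
    for _ in range(2000):
        p = ModelParams(kind="FBM", D=D, N=lag_steps + 1, dt=dt, H=H, alpha=2 * H)
        t = simulate_fbm(p, rng)
        disp2.append(t.xs[-1] ** 2 + t.ys[-1] ** 2)
    expected = 4 * D * (lag_steps * dt) ** (2 * H)
    assert abs(np.mean(disp2) - expected) / expected < 0.05


def test_fbm_rejects_supradiffusive_hurst_by_default(rng):
    p = ModelParams(kind="FBM", D=1.0, N=10, dt=0.1, H=0.7, alpha=1.4)
    with pytest.raises(ValueError, match="subdiffusive"):
        simulate_fbm(p, rng)


# ---------------------------------------------------------------------------
# localization noise
# ---------------------------------------------------------------------------


def test_noise_sigma_from_snr_formulas():
    p_nd = _nd_params(D=1.0, N=100)
    assert noise_sigma_from_snr(1.0, p_nd) == pytest.approx(0.18257, abs=1e-5)
    p_dm0 = ModelParams(kind="DM", D=1.0, N=100, dt=1 / 30, v=0.0, beta=0.0)
    assert noise_sigma_from_snr(3.0, p_dm0) == pytest.approx(
        noise_sigma_from_snr(3.0, p_nd)
    )
    p_dm = ModelParams(kind="DM", D=1.0, N=100, dt=1 / 30, v=2.0, beta=0.0)
    assert noise_sigma_from_snr(3.0, p_dm) == pytest.approx(
        math.sqrt(1 / 30 + (2 / 30) ** 2) / 3.0
    )
    assert noise_sigma_from_snr(1e12, p_nd) < 1e-6
    with pytest.raises(ValueError):
        noise_sigma_from_snr(0.0, p_nd)


def test_add_noise_statistics(rng):
    traj = simulate_nd(_nd_params(N=100_000), rng)
    noisy = add_noise(traj, 0.1, rng)
    dx = noisy.xs - traj.xs
    dy = noisy.ys - traj.ys
    n = len(dx)
    se_var = 0.01 * math.sqrt(2 / n)
    assert abs(dx.var() - 0.01) < 3 * se_var
    assert abs(dy.var() - 0.01) < 3 * se_var
    assert abs(np.corrcoef(dx, dy)[0, 1]) < 0.02
    assert np.allclose(noisy.times, traj.times)
    same = add_noise(traj, 0.0, rng)
    assert np.array_equal(same.xs, traj.xs)
    with pytest.raises(ValueError):
        add_noise(traj, -0.1, rng)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kind", CLASSES)
def test_identical_seeds_give_bit_identical_trajectories(kind):
    config = SimulationConfig(range_N=(30, 60))
    outs = []
    for _ in range(2):
        rng = child_rng(42, 7)
        p = sample_model_params(kind, config, rng)
        traj = add_noise(simulate(p, rng), p.sigma_noise, rng)
        outs.append(traj)
    assert np.array_equal(outs[0].xs, outs[1].xs)
    assert np.array_equal(outs[0].ys, outs[1].ys)
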