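"""Synthetic trapped-particle trajectories and detector signals.

Simulates an optically trapped microsphere as a per-axis overdamped
Ornstein--Uhlenbeck process whose drag coefficient grows as a molecular
layer accumulates on the particle surface, and renders the trajectory
into quadrant-photodiode-like X / Y / SUM channels whose total-intensity
gain may shift with surface coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .constants import BOLTZMANN

__all__ = [
    "TrapConfig",
    "BindingSchedule",
    "SimConfig",
    "Trajectory",
    "QPDRecord",
    "stokes_drag",
    "bound_fraction",
    "gamma_schedule",
    "simulate_trajectory",
    "render_qpd",
]

_INTEGRATORS = ("overdamped_exact", "euler_maruyama")


@dataclass(frozen=True)
class TrapConfig:
    """Trap and medium parameters.

    Parameters
    ----------
    temperature : float
        Bath temperature in kelvin. Must lie in the [273, 373] K sanity band.
    viscosity : float
        Dynamic viscosity of the medium in Pa*s (default: water at 25 C).
    stiffness_x, stiffness_y : float
        Harmonic trap stiffness per lateral axis, N/m.
    bare_radius : float
        Radius of the uncoated particle, m.
    boltzmann_constant : float
        kB in J/K; overridable only for testing.
    """

    temperature: float = 298.15
    viscosity: float = 8.9e-4
    stiffness_x: float = 1.0e-5
    stiffness_y: float = 1.0e-5
    bare_radius: float = 2.4e-6
    boltzmann_constant: float = BOLTZMANN

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "stiffness_x", "stiffness_y",
                     "bare_radius", "boltzmann_constant"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TrapConfig.{name} must be strictly positive")
        if not 273.0 <= self.temperature <= 373.0:
            raise ValueError(
                f"temperature {self.temperature} K outside [273, 373] K sanity band"
            )

    def stiffness(self, axis: str) -> float:
        if axis == "x":
            return self.stiffness_x
        if axis == "y":
            return self.stiffness_y
        raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class BindingSchedule:
    """Pseudo-first-order association schedule for the surface layer.

    The observed rate is ``kobs = kon * ligand_conc + koff``; the bound
    fraction follows ``1 - exp(-kobs * (t - start_time))`` for
    ``t >= start_time``. ``layer_thickness`` is the added hydrodynamic
    layer at full coverage.
    """

    kon: float = 0.0              # M^-1 s^-1
    koff: float = 0.0             # s^-1
    ligand_conc: float = 0.0      # M
    layer_thickness: float = 0.0  # m
    start_time: float = 0.0       # s

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "ligand_conc", "layer_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"BindingSchedule.{name} must be non-negative")

    @property
    def kobs(self) -> float:
        """Observed association rate, s^-1."""
        return self.kon * self.ligand_conc + self.koff


@dataclass(frozen=True)
class SimConfig:
    """Acquisition / detector model parameters.

    ``sum_coupling`` is the fractional SUM-channel change at full surface
    coverage (phenomenological detection-gain shift); ``noise_floor`` is
    the one-sided PSD level of additive white detector noise in
    (detector units)^2/Hz.
    """

    sampling_rate: float = 10_000.0
    duration: float = 600.0
    seed: int = 0
    integrator: str = "overdamped_exact"
    gain_x: float = 1.0
    gain_y: float = 1.0
    sum_baseline: float = 1.0
    sum_coupling: float = 0.0
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sum_baseline <= 0:
            raise ValueError("sum_baseline must be positive")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")
        if self.integrator not in _INTEGRATORS:
            raise ValueError(f"integrator must be one of {_INTEGRATORS}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class Trajectory:
    """Simulated bead displacement on a uniform time grid.

    x, y are displacements from the trap centre in metres; ``gamma_true``
    is the instantaneous drag coefficient used at each sample.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    gamma_true: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.gamma_true) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6):
                raise ValueError("times must be uniformly spaced at 1/sampling_rate")
        if np.any(self.gamma_true <= 0):
            raise ValueError("gamma_true must be positive everywhere")


@dataclass
class QPDRecord:
    """Detector channels X, Y, SUM sampled at ``sampling_rate``."""

    times: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    SUM: np.ndarray
    sampling_rate: float
    particle_id: str = "sim"

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.X) == len(self.Y) == len(self.SUM) == n):
            raise ValueError("QPD channels must have equal length")
        if np.any(self.SUM <= 0):
            idx = int(np.argmax(self.SUM <= 0))
            raise ValueError(f"SUM must be strictly positive (first violation at sample {idx})")

    @property
    def duration(self) -> float:
        return len(self.times) / self.sampling_rate


def stokes_drag(radius: float, viscosity: float) -> float:
    """Drag coefficient of a sphere, ``6 * pi * viscosity * radius`` (N*s/m)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return 6.0 * math.pi * viscosity * radius


def bound_fraction(schedule: BindingSchedule, t):
    """Fractional surface coverage at time(s) ``t``.

    Returns ``1 - exp(-kobs * max(0, t - start_time))``, i.e. the complex
    amount relative to its saturation value. Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    tau = np.maximum(0.0, t - schedule.start_time)
    out = -np.expm1(-schedule.kobs * tau)
    return out if out.ndim else float(out)


def gamma_schedule(trap: TrapConfig, schedule: BindingSchedule, times) -> np.ndarray:
    """Drag coefficient series: Stokes drag of the bare radius plus the
    coverage-weighted layer thickness at each time."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing")
    frac = np.atleast_1d(bound_fraction(schedule, times))
    radius = trap.bare_radius + schedule.layer_thickness * frac
    return 6.0 * math.pi * trap.viscosity * radius


def _axis_streams(seed: int) -> list[np.random.Generator]:
    """Named substreams (x, y, det_x, det_y, det_sum) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def _ou_chunked(
    noise_rng: np.random.Generator,
    gamma: np.ndarray,
    k: float,
    kBT: float,
    dt: float,
    chunk: int,
    exact: bool,
) -> np.ndarray:
    """AR(1) recursion with gamma frozen per chunk (quasi-static: gamma
    varies over minutes, trap relaxation is ~ms)."""
    n = len(gamma)
    out = np.empty(n)
    # start from the stationary distribution at the initial drag
    x_prev = math.sqrt(kBT / k) * noise_rng.standard_normal()
    xi = noise_rng.standard_normal(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        g = float(gamma[(lo + hi) // 2 if hi - lo > 1 else lo])
        if exact:
            a = math.exp(-k * dt / g)
            sigma = math.sqrt(kBT / k * (1.0 - a * a))
        else:
            step = k * dt / g
            if step >= 1.0:
                raise ValueError(
                    f"euler_maruyama unstable: stiffness*dt/gamma = {step:.3g} >= 1; "
                    "raise sampling_rate or use overdamped_exact"
                )
            a = 1.0 - step
            sigma = math.sqrt(2.0 * kBT * dt / g)
        block, zf = lfilter([1.0], [1.0, -a], sigma * xi[lo:hi], zi=[a * x_prev])
        out[lo:hi] = block
        x_prev = block[-1]
    return out


def simulate_trajectory(
    trap: TrapConfig, schedule: BindingSchedule, sim: SimConfig
) -> Trajectory:
    """Simulate per-axis overdamped motion in the harmonic trap.

    The default integrator uses the exact one-step Ornstein--Uhlenbeck
    update (no discretisation bias, no step-size restriction); the
    Euler--Maruyama cross-check integrator refuses steps with
    ``stiffness * dt / gamma >= 1``. Each axis draws from an independent
    substream of the master seed, so axes are uncorrelated and the output
    is bit-reproducible for a fixed configuration.
    """
    n = sim.n_samples
    if n < 1:
        raise ValueError("duration * sampling_rate must be >= 1 sample")
    dt = 1.0 / sim.sampling_rate
    times = np.arange(n) * dt
    gamma = gamma_schedule(trap, schedule, times)
    kBT = trap.boltzmann_constant * trap.temperature
    exact = sim.integrator == "overdamped_exact"
    chunk = max(1, int(round(0.1 * sim.sampling_rate)))
    rng_x, rng_y, *_ = _axis_streams(sim.seed)
    x = _ou_chunked(rng_x, gamma, trap.stiffness_x, kBT, dt, chunk, exact)
    y = _ou_chunked(rng_y, gamma, trap.stiffness_y, kBT, dt, chunk, exact)
    return Trajectory(times=times, x=x, y=y, gamma_true=gamma,
                      sampling_rate=sim.sampling_rate)


def render_qpd(
    traj: Trajectory,
    sim: SimConfig,
    schedule: BindingSchedule | None = None,
    particle_id: str = "sim",
) -> QPDRecord:
    """Render a trajectory into detector channels.

    ``X = gain_x * x + noise`` (likewise Y); ``SUM`` is the baseline total
    intensity scaled by ``1 + sum_coupling * bound_fraction(t)`` plus
    noise. Additive white noise has one-sided PSD ``noise_floor``, i.e.
    per-sample standard deviation ``sqrt(noise_floor * fs / 2)``.
    """
    if schedule is None:
        schedule = BindingSchedule()
    frac = np.atleast_1d(bound_fraction(schedule, traj.times))
    _, _, rng_dx, rng_dy, rng_ds = _axis_streams(sim.seed)
    n = len(traj.times)
    sigma = math.sqrt(sim.noise_floor * sim.sampling_rate / 2.0)
    X = sim.gain_x * traj.x
    Y = sim.gain_y * traj.y
    SUM = sim.sum_baseline * (1.0 + sim.sum_coupling * frac)
    if sigma > 0:
        X = X + sigma * rng_dx.standard_normal(n)
        Y = Y + sigma * rng_dy.standard_normal(n)
        SUM = SUM + sigma * rng_ds.standard_normal(n)
    else:
        SUM = SUM.copy()
    if np.any(SUM <= 0):
        raise ValueError(
            "detector configuration produced non-positive SUM samples; "
            "increase sum_baseline or reduce noise_floor"
        )
    return QPDRecord(times=traj.times.copy(), X=np.asarray(X), Y=np.asarray(Y),
                     SUM=SUM, sampling_rate=traj.sampling_rate,
                     particle_id=particle_id)
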