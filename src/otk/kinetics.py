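"""Binding-kinetics inference from effective-friction trajectories.

Implements per-particle max normalisation, moving-average smoothing,
time-windowed kernel-density summaries, sigmoid fitting of

    gamma(t) = b / (c + exp(-Kobs * (t - t0)))

to extract the observed association rate Kobs, and the pseudo-first-order
conversion kon = (Kobs - koff) / [L].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde

from .spectral import GammaTrajectory, SegmentEstimate

__all__ = [
    "KineticFit",
    "RateResult",
    "WindowDensity",
    "normalize_to_max",
    "moving_average",
    "smooth_trajectory",
    "kde_summary",
    "binding_curve",
    "fit_binding_sigmoid",
    "association_rate",
]


@dataclass
class KineticFit:
    """Sigmoid-fit result.

    The model has an exact gauge freedom (scaling b and c together while
    shifting t0 leaves the curve unchanged), so by default c is pinned to
    1 and the fit has three free parameters; ``identifiable`` is False
    when the Kobs standard error exceeds the estimate (flat series).
    """

    kobs: float
    t0: float
    b: float
    c: float
    r_squared: float
    rmse: float
    kobs_stderr: float
    covariance: np.ndarray
    identifiable: bool
    at_bound: bool = False
    n_points: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.b / (self.c + np.exp(-self.kobs * (t - self.t0)))


@dataclass(frozen=True)
class RateResult:
    """Association rate constant with the assumption it carries."""

    kon: float
    koff_assumed: float
    ligand_conc: float
    kd_implied: float | None

    def __post_init__(self) -> None:
        if self.kon < 0:
            raise ValueError("kon must be non-negative")


@dataclass
class WindowDensity:
    """Gaussian-KDE summary of gamma_star values in one time window."""

    t_start: float
    t_end: float
    grid: np.ndarray
    density: np.ndarray
    mean: float
    std: float
    n: int


def normalize_to_max(traj: GammaTrajectory) -> GammaTrajectory:
    """Divide each axis by its own maximum over converged segments.

    Idempotent; raises if an axis has no converged segment.
    """
    new_axes: dict[str, list[SegmentEstimate]] = {}
    for axis, ests in traj.axes.items():
        vals = [e.gamma_star for e in ests if e.converged]
        if not vals:
            raise ValueError(f"axis {axis!r} has no converged segments to normalize")
        peak = max(vals)
        new_axes[axis] = [
            replace(e, gamma_star=e.gamma_star / peak) if e.converged else replace(e)
            for e in ests
        ]
    return GammaTrajectory(particle_id=traj.particle_id, axes=new_axes, normalized=True)


def moving_average(times, values, window: int = 20):
    """Sliding mean and standard deviation over ``window`` consecutive points.

    Returns ``(t_center, mean, std)`` with ``len(values) - window + 1``
    output points; the timestamp is the mean time of each window.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(values) < window:
        raise ValueError(f"series length {len(values)} shorter than window {window}")
    v = np.lib.stride_tricks.sliding_window_view(values, window)
    t = np.lib.stride_tricks.sliding_window_view(times, window)
    return t.mean(axis=1), v.mean(axis=1), v.std(axis=1, ddof=0)


def smooth_trajectory(traj: GammaTrajectory, axis: str = "x", window: int = 20):
    """Moving average over the converged estimates of one axis."""
    ok = traj.converged(axis)
    return moving_average(traj.t_mid(axis)[ok], traj.gamma(axis)[ok], window)


def kde_summary(traj: GammaTrajectory, window_duration: float | None = None,
                axis: str = "x", grid_size: int = 512) -> list[WindowDensity]:
    """Gaussian-kernel density of gamma_star per time window.

    Windows default to thirds of the record (early / middle / late).
    Bandwidth follows Scott's rule. Windows with fewer than two points are
    skipped with a warning; each returned density integrates to 1.
    """
    ok = traj.converged(axis)
    t = traj.t_mid(axis)[ok]
    g = traj.gamma(axis)[ok]
    if t.size == 0:
        raise ValueError("no converged estimates to summarize")
    span = t.max() - t.min()
    if window_duration is None:
        window_duration = span / 3.0 if span > 0 else 1.0
    edges = np.arange(t.min(), t.max() + window_duration, window_duration)
    if edges[-1] < t.max() + 1e-12:
        edges = np.append(edges, t.max() + 1e-12)
    out: list[WindowDensity] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi) if hi < edges[-1] else (t >= lo) & (t <= hi)
        vals = g[sel]
        if vals.size < 2 or np.ptp(vals) == 0:
            warnings.warn(f"KDE window [{lo:.1f}, {hi:.1f}] s has < 2 distinct points; skipped")
            continue
        kde = gaussian_kde(vals, bw_method="scott")
        pad = 3.0 * vals.std(ddof=1)
        grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_size)
        dens = kde(grid)
        out.append(WindowDensity(t_start=float(lo), t_end=float(hi), grid=grid,
                                 density=dens, mean=float(vals.mean()),
                                 std=float(vals.std(ddof=1)), n=int(vals.size)))
    return out


def binding_curve(lr_max: float, kon: float, koff: float, ligand_conc: float, t):
    """Complex amount ``LRmax * (1 - exp(-(kon*[L] + koff) * t))``."""
    for name, v in (("lr_max", lr_max), ("kon", kon), ("koff", koff),
                    ("ligand_conc", ligand_conc)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    t = np.asarray(t, dtype=float)
    out = lr_max * -np.expm1(-(kon * ligand_conc + koff) * t)
    return out if out.ndim else float(out)


def _sigmoid_resid(theta, t, y, fix_c):
    if fix_c:
        k, t0, b = theta
        c = 1.0
    else:
        k, t0, b, c = theta
    return b / (c + np.exp(np.clip(-k * (t - t0), -700, 700))) - y


_KOBS_BOUNDS = (1e-12, 1e6)


def fit_binding_sigmoid(times, values, fix_c: bool = True,
                        min_efoldings: float = 3.0) -> KineticFit:
    """Nonlinear least-squares fit of the saturating sigmoid.

    Multi-start: t0 gridded over the observed span (5 candidates), with
    the Kobs start taken from the maximum slope of the series. Warns when
    the record spans fewer than ``min_efoldings`` of the fitted rise.
    Raises on total non-convergence; a Kobs estimate at its bound, or a
    standard error exceeding the estimate, marks the fit non-identifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    n = len(t)
    nfree = 3 if fix_c else 4
    if n < nfree + 2:
        raise ValueError("too few points for the sigmoid fit")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("times must span a positive interval")

    # slope-based rate start (logistic max slope = K * plateau / 4)
    dy = np.gradient(y, t)
    rng_y = np.ptp(y)
    k0 = 4.0 * float(np.max(np.abs(dy))) / rng_y if rng_y > 0 else 1.0 / span
    k0 = float(np.clip(k0, 10 / span / n, 10.0 / (t[1] - t[0] + 1e-300)))
    b0 = float(np.max(y)) if np.max(y) != 0 else 1.0

    best = None
    for q in (0.05, 0.25, 0.5, 0.75, 0.95):
        t0_start = t[0] + q * span
        x0 = [k0, t0_start, b0] if fix_c else [k0, t0_start, b0, 1.0]
        lb = [_KOBS_BOUNDS[0], t[0] - 10 * span, -np.inf] + ([] if fix_c else [1e-12])
        ub = [_KOBS_BOUNDS[1], t[-1] + 10 * span, np.inf] + ([] if fix_c else [np.inf])
        try:
            sol = least_squares(_sigmoid_resid, x0, args=(t, y, fix_c),
                                bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        if not sol.success:
            continue
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from every start")
    sol = best[1]
    if fix_c:
        k, t0, b = sol.x
        c = 1.0
    else:
        k, t0, b, c = sol.x

    resid = sol.fun
    dof = max(1, n - nfree)
    s2 = float(resid @ resid) / dof
    jtj = sol.jac.T @ sol.jac
    cov = s2 * np.linalg.pinv(jtj)
    k_se = float(math.sqrt(max(0.0, cov[0, 0])))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    rmse = float(math.sqrt(np.mean(resid**2)))
    at_bound = bool(np.isclose(k, _KOBS_BOUNDS[0]) or np.isclose(k, _KOBS_BOUNDS[1]))
    # a rise buried in the residual noise is not a measurable transition,
    # even when the local fit assigns Kobs a finite standard error
    amplitude = float(np.ptp(y + resid))
    identifiable = (k_se < abs(k)) and not at_bound and amplitude > 3.0 * rmse
    if identifiable and k * span < min_efoldings:
        warnings.warn(
            f"record spans only {k * span:.2f} e-foldings of the fitted rise "
            f"(< {min_efoldings}); Kobs may be poorly constrained"
        )
    return KineticFit(kobs=float(k), t0=float(t0), b=float(b), c=float(c),
                      r_squared=r2, rmse=rmse, kobs_stderr=k_se, covariance=cov,
                      identifiable=identifiable, at_bound=at_bound, n_points=n)


def association_rate(fit, ligand_conc: float, koff: float = 0.0) -> RateResult:
    """Convert an observed rate to kon = (Kobs - koff) / [L].

    ``fit`` may be a :class:`KineticFit` or a bare Kobs value. The default
    koff = 0 is valid only for ultra-high-affinity systems; the returned
    result records the assumption. Raises for non-positive [L] or for
    Kobs < koff (negative implied rate).
    """
    kobs = fit.kobs if isinstance(fit, KineticFit) else float(fit)
    if ligand_conc <= 0:
        raise ValueError("ligand concentration must be positive")
    if koff < 0:
        raise ValueError("koff must be non-negative")
    if kobs < koff:
        raise ValueError(f"Kobs ({kobs:g}) < koff ({koff:g}): negative association rate")
    kon = (kobs - koff) / ligand_conc
    kd = koff / kon if (koff > 0 and kon > 0) else None
    return RateResult(kon=kon, koff_assumed=koff, ligand_conc=ligand_conc,
                      kd_implied=kd)
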