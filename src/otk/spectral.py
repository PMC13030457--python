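"""Per-segment power-spectral-density analysis of detector signals.

Pipeline: normalise X and Y to the SUM channel, discard the initial
transient, cut the record into fixed-length segments, compute each
segment's one-sided PSD, and fit the Lorentzian

    P(f) = D / (2 * pi^2 * (fc^2 + f^2))

to extract a diffusion scale D, a corner frequency fc, and an effective
friction coefficient ``gamma_star = kB*T / D``. Because the channels are
SUM-normalised, gamma_star is a scaled proxy that mixes hydrodynamic drag
with detection-gain changes; only relative variations are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares
from scipy.special import digamma

from .constants import BOLTZMANN

__all__ = [
    "SpectralConfig",
    "PsdEstimate",
    "SegmentEstimate",
    "GammaTrajectory",
    "preprocess",
    "segment",
    "compute_psd",
    "fit_lorentzian",
    "gamma_trajectory",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for the segment-wise PSD estimation chain.

    ``fit_band`` bounds the Lorentzian fit; a ``None`` upper bound means
    ``sampling_rate / 8``: the sampled process has an aliased (AR(1))
    spectrum that is measurably flatter than a Lorentzian above that, and
    fitting into it biases fc upward by several percent.
    ``temperature`` enters only through ``gamma_star = kB*T / D``.
    """

    segment_length: float = 1.0      # s
    discard_initial: float = 30.0    # s
    fit_band: tuple[float, float | None] = (5.0, None)
    psd_averaging: str = "single_periodogram"
    welch_subblocks: int = 4
    fit_space: str = "log_least_squares"
    #: correct the known negative bias of log-periodogram ordinates
    #: (exp(log n - digamma(n))); disable when fitting noiseless spectra
    log_bias_correction: bool = True
    temperature: float = 298.15
    boltzmann_constant: float = BOLTZMANN

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be non-negative")
        if self.fit_band[0] <= 0:
            raise ValueError("fit_band lower edge must be positive")
        if self.psd_averaging not in ("single_periodogram", "welch_subblocks"):
            raise ValueError("unknown psd_averaging mode")
        if self.fit_space not in ("log_least_squares", "weighted_linear"):
            raise ValueError("unknown fit_space mode")

    def band_for(self, sampling_rate: float) -> tuple[float, float]:
        lo, hi = self.fit_band
        if hi is None:
            hi = sampling_rate / 8.0
        if hi > sampling_rate / 2.0:
            raise ValueError("fit band upper edge exceeds the Nyquist frequency")
        if hi <= lo:
            raise ValueError("fit band is empty")
        return float(lo), float(hi)


@dataclass
class PsdEstimate:
    """One-sided PSD on a positive frequency grid (DC bin excluded)."""

    frequencies: np.ndarray
    power: np.ndarray
    n_averages: int = 1

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.power):
            raise ValueError("frequency and power grids differ in length")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SegmentEstimate:
    """Lorentzian-fit output for one segment of one axis."""

    t_mid: float
    diffusion_scale: float
    corner_frequency: float
    gamma_star: float
    fit_residual: float
    converged: bool


@dataclass
class GammaTrajectory:
    """Time-ordered per-axis sequences of segment estimates."""

    particle_id: str
    axes: dict[str, list[SegmentEstimate]]
    normalized: bool = False

    def axis_names(self) -> list[str]:
        return list(self.axes)

    def t_mid(self, axis: str) -> np.ndarray:
        return np.array([e.t_mid for e in self.axes[axis]])

    def gamma(self, axis: str) -> np.ndarray:
        return np.array([e.gamma_star for e in self.axes[axis]])

    def converged(self, axis: str) -> np.ndarray:
        return np.array([e.converged for e in self.axes[axis]], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis, ests in self.axes.items():
            for e in ests:
                rows.append(
                    dict(t_mid=e.t_mid, axis=axis, D=e.diffusion_scale,
                         fc=e.corner_frequency, gamma_star=e.gamma_star,
                         residual=e.fit_residual, converged=e.converged)
                )
        return pd.DataFrame(rows, columns=["t_mid", "axis", "D", "fc",
                                           "gamma_star", "residual", "converged"])


def preprocess(qpd, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """SUM-normalise X and Y and drop the initial transient.

    Returns ``(X/SUM, Y/SUM)`` with the first ``discard_initial`` seconds
    removed. Raises on any non-positive SUM sample (naming its index) and
    on records not longer than the discard window.
    """
    bad = np.flatnonzero(np.asarray(qpd.SUM) <= 0)
    if bad.size:
        raise ValueError(f"non-positive SUM at sample {bad[0]}")
    n_skip = int(round(cfg.discard_initial * qpd.sampling_rate))
    if len(qpd.times) <= n_skip:
        raise ValueError(
            f"record ({len(qpd.times)} samples) is not longer than the "
            f"{cfg.discard_initial} s discard window"
        )
    xn = np.asarray(qpd.X[n_skip:]) / np.asarray(qpd.SUM[n_skip:])
    yn = np.asarray(qpd.Y[n_skip:]) / np.asarray(qpd.SUM[n_skip:])
    return xn, yn


def segment(channel: np.ndarray, cfg: SpectralConfig, sampling_rate: float) -> np.ndarray:
    """Cut a channel into contiguous non-overlapping equal-length blocks.

    Returns a 2-D array of shape (n_blocks, block_length); the trailing
    partial block is dropped.
    """
    block = int(round(cfg.segment_length * sampling_rate))
    channel = np.asarray(channel)
    if len(channel) < block:
        raise ValueError(
            f"channel ({len(channel)} samples) shorter than one "
            f"{cfg.segment_length} s segment ({block} samples)"
        )
    n_blocks = len(channel) // block
    return channel[: n_blocks * block].reshape(n_blocks, block)


def compute_psd(block: np.ndarray, sampling_rate: float,
                cfg: SpectralConfig | None = None) -> PsdEstimate:
    """One-sided PSD of a single segment, DC bin excluded.

    Default is a single rectangular-window periodogram (maximal frequency
    resolution; the sum of the returned power times the bin width equals
    the block variance — Parseval). Welch sub-block averaging is optional.
    """
    cfg = cfg or SpectralConfig()
    block = np.asarray(block, dtype=float)
    if block.ndim != 1 or len(block) < 2:
        raise ValueError("block must be a 1-D array of length >= 2")
    if cfg.psd_averaging == "welch_subblocks":
        nper = max(2, len(block) // cfg.welch_subblocks)
        f, p = signal.welch(block, fs=sampling_rate, window="boxcar",
                            nperseg=nper, noverlap=0, detrend="constant")
        n_avg = len(block) // nper
    else:
        f, p = signal.periodogram(block, fs=sampling_rate, window="boxcar",
                                  detrend="constant")
        n_avg = 1
    return PsdEstimate(frequencies=f[1:], power=p[1:], n_averages=n_avg)


def _lorentzian(f: np.ndarray, D: float, fc: float) -> np.ndarray:
    return D / (2.0 * math.pi**2 * (fc**2 + f**2))


def _init_guess(f: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Deterministic data-driven start: plateau from the low-frequency end,
    fc from the half-power crossing of a smoothed spectrum."""
    w = min(15, max(1, len(p) // 10))
    smooth = np.convolve(p, np.ones(w) / w, mode="same")
    n_lo = max(3, len(p) // 50)
    plateau = float(np.median(smooth[:n_lo]))
    if plateau <= 0:
        plateau = float(np.mean(p)) or 1.0
    below = np.flatnonzero(smooth <= plateau / 2.0)
    if below.size:
        fc0 = float(f[below[0]])
    else:
        fc0 = float(math.sqrt(f[0] * f[-1]))
    fc0 = min(max(fc0, f[0]), f[-1])
    D0 = plateau * 2.0 * math.pi**2 * fc0**2
    return D0, fc0


def fit_lorentzian(psd: PsdEstimate, cfg: SpectralConfig | None = None,
                   sampling_rate: float | None = None,
                   t_mid: float = math.nan) -> SegmentEstimate:
    """Fit the Lorentzian model over the configured band.

    Default fit is unweighted least squares on log(power), which
    stabilises the heavy-tailed periodogram noise; the fitted D is
    corrected for the known negative bias of the log of an averaged
    periodogram (``log(n) - digamma(n)``). The ``weighted_linear``
    cross-check regresses 1/P on f^2 with weights P^2.

    gamma_star is recovered as ``kB*T / D`` in the normalised-unit
    convention and must be read as a scaled proxy. Non-convergence, or a
    corner frequency escaping the fit band, yields ``converged=False``.
    """
    cfg = cfg or SpectralConfig()
    if sampling_rate is None:
        # infer Nyquist from the grid itself (bins extend to fs/2)
        sampling_rate = 2.0 * float(psd.frequencies[-1])
    lo, hi = cfg.band_for(sampling_rate)
    mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if mask.sum() < 10:
        raise ValueError(f"fit band [{lo}, {hi}] Hz holds {int(mask.sum())} bins; >= 10 required")
    f = psd.frequencies[mask]
    # the Lorentzian model is the two-sided density; the estimate is
    # one-sided, so halve it to keep D = kB*T/gamma in physical units
    p = psd.power[mask] / 2.0
    kBT = cfg.boltzmann_constant * cfg.temperature

    def _failed(residual: float = math.inf) -> SegmentEstimate:
        return SegmentEstimate(t_mid=t_mid, diffusion_scale=math.nan,
                               corner_frequency=math.nan, gamma_star=math.nan,
                               fit_residual=residual, converged=False)

    if cfg.fit_space == "weighted_linear":
        # 1/P = (2 pi^2 / D) * (fc^2 + f^2), weighted by P^2
        pos = p > 0
        if pos.sum() < 10:
            return _failed()
        fp, pp = f[pos], p[pos]
        w = pp**2
        X = np.column_stack([np.ones_like(fp), fp**2])
        y = 1.0 / pp
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            return _failed()
        alpha, slope = beta
        if slope <= 0 or alpha <= 0:
            return _failed()
        D = 2.0 * math.pi**2 / slope
        fc = math.sqrt(alpha / slope)
        resid = y - X @ beta
        residual = float(np.sqrt(np.average(resid**2, weights=w)) * np.mean(pp))
    else:
        pos = p > 0
        if pos.sum() < 10:
            return _failed()
        fp = f[pos]
        logp = np.log(p[pos])
        D0, fc0 = _init_guess(fp, p[pos])

        def resid_fn(theta):
            logD, logfc = theta
            fc_ = math.exp(logfc)
            return logp - (logD - math.log(2.0 * math.pi**2) - np.log(fc_**2 + fp**2))

        sol = least_squares(resid_fn, x0=[math.log(max(D0, 1e-300)), math.log(fc0)],
                            method="lm", max_nfev=200)
        if not sol.success:
            return _failed(float(np.sqrt(np.mean(sol.fun**2))))
        D = math.exp(sol.x[0])
        fc = math.exp(sol.x[1])
        if cfg.log_bias_correction:
            # E[log of n-averaged periodogram] = log(true) + digamma(n) - log(n)
            n = max(1, psd.n_averages)
            D *= math.exp(math.log(n) - digamma(n))
        residual = float(np.sqrt(np.mean(sol.fun**2)))

    converged = bool(np.isfinite(D) and np.isfinite(fc) and D > 0 and lo < fc < hi)
    gamma_star = kBT / D if converged else math.nan
    return SegmentEstimate(t_mid=t_mid, diffusion_scale=D if converged else math.nan,
                           corner_frequency=fc if converged else math.nan,
                           gamma_star=gamma_star, fit_residual=residual,
                           converged=converged)


def gamma_trajectory(qpd, cfg: SpectralConfig | None = None,
                     axes: tuple[str, ...] = ("x", "y")) -> GammaTrajectory:
    """Full estimation chain: preprocess -> segment -> PSD -> Lorentzian fit.

    Returns per-axis estimate sequences ordered by segment midpoint time.
    Non-converged segments are retained but flagged; if every segment of
    every requested axis fails, an error is raised.
    """
    cfg = cfg or SpectralConfig()
    xn, yn = preprocess(qpd, cfg)
    channels = {"x": xn, "y": yn}
    block_len = int(round(cfg.segment_length * qpd.sampling_rate))
    out: dict[str, list[SegmentEstimate]] = {}
    n_ok = 0
    for axis in axes:
        if axis not in channels:
            raise ValueError(f"unknown axis {axis!r}")
        blocks = segment(channels[axis], cfg, qpd.sampling_rate)
        ests = []
        for i, block in enumerate(blocks):
            t_mid = cfg.discard_initial + (i + 0.5) * block_len / qpd.sampling_rate
            psd = compute_psd(block, qpd.sampling_rate, cfg)
            est = fit_lorentzian(psd, cfg, sampling_rate=qpd.sampling_rate, t_mid=t_mid)
            ests.append(est)
            n_ok += est.converged
        out[axis] = ests
    if n_ok == 0:
        raise RuntimeError("all segments failed to converge; no usable estimates")
    return GammaTrajectory(particle_id=qpd.particle_id, axes=out)
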