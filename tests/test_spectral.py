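import math

import numpy as np
import pytest

import otk
from otk.spectral import PsdEstimate, _lorentzian

from conftest import FC_BEAD, GAMMA_BEAD


def exact_one_sided_lorentzian(f, D, fc):
    """One-sided counterpart of the two-sided model density."""
    return 2.0 * _lorentzian(np.asarray(f, dtype=float), D, fc)


def grid_search_fit(f, power, f_lo, f_hi, d_grid, fc_grid):
    """Brute-force oracle: minimise the same log-space cost over a grid."""
    mask = (f >= f_lo) & (f <= f_hi)
    fp, pp = f[mask], power[mask] / 2.0
    best = (np.inf, None, None)
    for D in d_grid:
        for fc in fc_grid:
            r = np.log(pp) - np.log(_lorentzian(fp, D, fc))
            cost = float(r @ r)
            if cost < best[0]:
                best = (cost, D, fc)
    return best[1], best[2]


class TestPreprocess:
    def test_identity_channel(self, fast_spectral_cfg):
        n = 100_000
        t = np.arange(n) / 1e4
        s = np.full(n, 3.0)
        qpd = otk.QPDRecord(times=t, X=s.copy(), Y=np.ones(n), SUM=s,
                            sampling_rate=1e4)
        xn, yn = otk.preprocess(qpd, fast_spectral_cfg)
        assert np.all(xn == 1.0)
        assert len(xn) == n - 50_000  # 5 s discard at 10 kHz

    def test_segment_count_arithmetic(self):
        # 600 s record, 30 s discard, 1 s segments -> 570 segments
        cfg = otk.SpectralConfig()
        n_segments = int((600 - cfg.discard_initial) / cfg.segment_length)
        assert n_segments == 570

    def test_short_record_rejected(self, short_qpd):
        cfg = otk.SpectralConfig(discard_initial=1e4)
        with pytest.raises(ValueError, match="discard"):
            otk.preprocess(short_qpd, cfg)

    def test_zero_sum_rejected(self, fast_spectral_cfg):
        n = 100_000
        t = np.arange(n) / 1e4
        s = np.ones(n)
        s[123] = 0.0
        with pytest.raises(ValueError, match="123"):
            qpd = otk.QPDRecord(times=t, X=t, Y=t, SUM=s, sampling_rate=1e4)


class TestSegment:
    def test_floor_division(self, fast_spectral_cfg):
        blocks = otk.segment(np.zeros(55_000), fast_spectral_cfg, 1e4)
        assert blocks.shape == (5, 10_000)

    def test_single_block(self, fast_spectral_cfg):
        assert otk.segment(np.zeros(10_000), fast_spectral_cfg, 1e4).shape == (1, 10_000)

    def test_partition_property(self, fast_spectral_cfg):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(25_500)
        blocks = otk.segment(x, fast_spectral_cfg, 1e4)
        assert np.array_equal(blocks.ravel(), x[:20_000])

    def test_too_short(self, fast_spectral_cfg):
        with pytest.raises(ValueError, match="shorter"):
            otk.segment(np.zeros(9_999), fast_spectral_cfg, 1e4)


class TestComputePsd:
    def test_white_noise_level_and_parseval(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        psd = otk.compute_psd(x, 1e4)
        df = psd.frequencies[1] - psd.frequencies[0]
        # one-sided flat level for unit variance = 2 / fs
        assert psd.power.mean() == pytest.approx(2.0 / 1e4, rel=0.05)
        assert np.sum(psd.power) * df == pytest.approx(x.var(), rel=1e-6)

    def test_sinusoid_line(self):
        t = np.arange(10_000) / 1e4
        x = np.sin(2 * np.pi * 100.0 * t)
        psd = otk.compute_psd(x, 1e4)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(100.0)

    def test_zero_signal(self):
        psd = otk.compute_psd(np.zeros(1000), 1e4)
        assert np.all(psd.power == 0.0)

    def test_dc_excluded(self):
        psd = otk.compute_psd(np.ones(1000) + np.arange(1000) * 0.0, 1e4)
        assert psd.frequencies[0] > 0

    def test_welch_averaging(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        cfg = otk.SpectralConfig(psd_averaging="welch_subblocks", welch_subblocks=4)
        psd = otk.compute_psd(x, 1e4, cfg)
        assert psd.n_averages == 4
        assert len(psd.frequencies) < 5_000

    def test_rejects_tiny_block(self):
        with pytest.raises(ValueError):
            otk.compute_psd(np.zeros(1), 1e4)


class TestFitLorentzian:
    def test_noiseless_self_fit(self):
        f = np.arange(1.0, 5001.0)
        D, fc = 1e-3, 40.0
        psd = PsdEstimate(frequencies=f, power=exact_one_sided_lorentzian(f, D, fc))
        cfg = otk.SpectralConfig(log_bias_correction=False)
        est = otk.fit_lorentzian(psd, cfg, sampling_rate=1e4)
        assert est.converged
        assert est.diffusion_scale == pytest.approx(D, rel=1e-7)
        assert est.corner_frequency == pytest.approx(fc, rel=1e-7)

    def test_weighted_linear_self_fit(self):
        f = np.arange(1.0, 5001.0)
        D, fc = 2.5e-4, 55.0
        psd = PsdEstimate(frequencies=f, power=exact_one_sided_lorentzian(f, D, fc))
        cfg = otk.SpectralConfig(fit_space="weighted_linear")
        est = otk.fit_lorentzian(psd, cfg, sampling_rate=1e4)
        assert est.converged
        assert est.diffusion_scale == pytest.approx(D, rel=1e-9)
        assert est.corner_frequency == pytest.approx(fc, rel=1e-9)

    def test_half_power_point(self):
        # value at f = fc is half the zero-frequency plateau
        D, fc = 1e-3, 40.0
        assert _lorentzian(np.array([fc]), D, fc)[0] == pytest.approx(
            0.5 * D / (2 * math.pi**2 * fc**2))

    def test_gamma_star_convention(self):
        # gamma* = kB*T / D for the fitted D
        f = np.arange(1.0, 5001.0)
        D, fc = 1e-13, 40.0
        psd = PsdEstimate(frequencies=f, power=exact_one_sided_lorentzian(f, D, fc))
        cfg = otk.SpectralConfig(log_bias_correction=False)
        est = otk.fit_lorentzian(psd, cfg, sampling_rate=1e4)
        kBT = cfg.boltzmann_constant * cfg.temperature
        assert est.gamma_star == pytest.approx(kBT / D, rel=1e-6)

    def test_grid_search_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        f = np.arange(1.0, 2501.0)
        D, fc = 1e-3, 40.0
        power = exact_one_sided_lorentzian(f, D, fc) * rng.exponential(size=f.size)
        cfg = otk.SpectralConfig(log_bias_correction=False, fit_band=(5.0, 1250.0))
        est = otk.fit_lorentzian(psd := PsdEstimate(frequencies=f, power=power),
                                 cfg, sampling_rate=1e4)
        d_grid = est.diffusion_scale * np.linspace(0.9, 1.1, 41)
        fc_grid = est.corner_frequency * np.linspace(0.9, 1.1, 41)
        d_star, fc_star = grid_search_fit(f, power, 5.0, 1250.0, d_grid, fc_grid)
        # optimiser result must sit at the grid's own minimum
        assert d_star == pytest.approx(est.diffusion_scale, rel=0.01)
        assert fc_star == pytest.approx(est.corner_frequency, rel=0.01)

    def test_estimator_consistency(self):
        # error of the mean gamma* over n spectra shrinks ~ 1/sqrt(n)
        rng = np.random.default_rng(4)
        f = np.arange(1.0, 1251.0)
        D, fc = 1e-13, 40.0
        cfg = otk.SpectralConfig(fit_band=(5.0, 625.0))
        kBT = cfg.boltzmann_constant * cfg.temperature
        truth = kBT / D
        gs = []
        for _ in range(128):
            power = exact_one_sided_lorentzian(f, D, fc) * rng.exponential(size=f.size)
            est = otk.fit_lorentzian(PsdEstimate(frequencies=f, power=power),
                                     cfg, sampling_rate=2500.0)
            gs.append(est.gamma_star)
        gs = np.array(gs)
        err_small = np.abs(gs[:8].reshape(2, 4).mean(axis=1) / truth - 1).mean()
        err_big = abs(gs.mean() / truth - 1)
        assert err_big < 0.02                       # consistent (bias-corrected)
        assert err_big < err_small + 0.01           # error shrinks with n

    def test_nonconvergence_flagged(self):
        # spectrum rising with frequency cannot be a Lorentzian in-band
        f = np.arange(1.0, 2501.0)
        psd = PsdEstimate(frequencies=f, power=f**2)
        est = otk.fit_lorentzian(psd, otk.SpectralConfig(), sampling_rate=1e4)
        assert not est.converged
        assert math.isnan(est.gamma_star)

    def test_too_few_bins(self):
        f = np.linspace(10, 20, 5)
        psd = PsdEstimate(frequencies=f, power=np.ones(5))
        with pytest.raises(ValueError, match="10"):
            otk.fit_lorentzian(psd, otk.SpectralConfig(fit_band=(9.0, 21.0)),
                               sampling_rate=1e4)


class TestGammaTrajectory:
    def test_counts_and_order(self, short_gamma_traj, short_qpd, fast_spectral_cfg):
        n_expected = int((short_qpd.duration - fast_spectral_cfg.discard_initial)
                         / fast_spectral_cfg.segment_length)
        for ax in ("x", "y"):
            assert len(short_gamma_traj.axes[ax]) == n_expected
            t = short_gamma_traj.t_mid(ax)
            assert np.all(np.diff(t) > 0)

    def test_segment_fc_near_closed_form(self, short_gamma_traj):
        ok = short_gamma_traj.converged("x")
        fc = np.array([e.corner_frequency for e in short_gamma_traj.axes["x"]])[ok]
        assert np.median(fc) == pytest.approx(FC_BEAD, rel=0.10)

    def test_gamma_star_near_truth(self, short_gamma_traj):
        ok = short_gamma_traj.converged("x")
        gs = short_gamma_traj.gamma("x")[ok]
        assert np.median(gs) == pytest.approx(GAMMA_BEAD, rel=0.10)

    def test_parseval_per_segment(self, short_qpd, fast_spectral_cfg):
        xn, _ = otk.preprocess(short_qpd, fast_spectral_cfg)
        blocks = otk.segment(xn, fast_spectral_cfg, short_qpd.sampling_rate)
        for block in blocks[:10]:
            psd = otk.compute_psd(block, short_qpd.sampling_rate)
            df = psd.frequencies[1] - psd.frequencies[0]
            assert np.sum(psd.power) * df == pytest.approx(block.var(), rel=0.01)

    def test_scale_invariance(self, short_qpd, fast_spectral_cfg):
        scaled = otk.QPDRecord(times=short_qpd.times, X=short_qpd.X * 7.5,
                               Y=short_qpd.Y * 7.5, SUM=short_qpd.SUM * 7.5,
                               sampling_rate=short_qpd.sampling_rate)
        a = otk.gamma_trajectory(short_qpd, fast_spectral_cfg, axes=("x",))
        b = otk.gamma_trajectory(scaled, fast_spectral_cfg, axes=("x",))
        # X/SUM differs only in the last ulp after common rescaling
        np.testing.assert_allclose(a.gamma("x"), b.gamma("x"), rtol=1e-7)

    def test_to_frame_schema(self, short_gamma_traj):
        df = short_gamma_traj.to_frame()
        assert list(df.columns) == ["t_mid", "axis", "D", "fc", "gamma_star",
                                    "residual", "converged"]
        assert set(df["axis"]) == {"x", "y"}

    def test_all_failed_raises(self, fast_spectral_cfg):
        n = 100_000
        t = np.arange(n) / 1e4
        qpd = otk.QPDRecord(times=t, X=np.ones(n), Y=np.ones(n), SUM=np.ones(n),
                            sampling_rate=1e4)
        with pytest.raises(RuntimeError, match="converge"):
            otk.gamma_trajectory(qpd, fast_spectral_cfg)


class TestSpectralConfigValidation:
    def test_band_defaults_to_fs_over_8(self):
        cfg = otk.SpectralConfig()
        assert cfg.band_for(1e4) == (5.0, 1250.0)

    def test_band_above_nyquist_rejected(self):
        cfg = otk.SpectralConfig(fit_band=(5.0, 6000.0))
        with pytest.raises(ValueError, match="Nyquist"):
            cfg.band_for(1e4)

    def test_bad_modes(self):
        with pytest.raises(ValueError):
            otk.SpectralConfig(psd_averaging="multitaper")
        with pytest.raises(ValueError):
            otk.SpectralConfig(fit_space="bayes")
        with pytest.raises(ValueError):
            otk.SpectralConfig(segment_length=0.0)
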