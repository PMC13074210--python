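"""Photon-level Monte Carlo: streams, bursts, windows, histograms."""

import numpy as np
import pytest

from fretkin.fcsmodel import DetectionModel, MixtureModel
from fretkin.kinetics import build_rate_matrix, mean_efficiency
from fretkin.simulate import (
    PhotonStream,
    SimulationConfig,
    detect_bursts,
    histogram2d,
    simulate_stream,
    timewindow_histograms,
    window_counts,
)


def small_cfg(seed=0, **kw):
    defaults = dict(
        E=np.array([0.5]), mixture=None, x_s=np.array([1.0]),
        det=DetectionModel(t_diff=1.5, Q0=300.0),
        n_molecules=10, duration_s=4.0, dt_us=5.0, seed=seed, box_xy=8.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateStream:
    def test_fixed_seed_bit_identical(self):
        s1 = simulate_stream(small_cfg(seed=3))
        s2 = simulate_stream(small_cfg(seed=3))
        assert np.array_equal(s1.macro_ms, s2.macro_ms)
        assert np.array_equal(s1.channel, s2.channel)
        assert np.array_equal(s1.micro_ns, s2.micro_ns)

    def test_different_seed_differs(self):
        s1 = simulate_stream(small_cfg(seed=3))
        s2 = simulate_stream(small_cfg(seed=4))
        assert len(s1) != len(s2) or not np.array_equal(s1.macro_ms, s2.macro_ms)

    def test_macro_sorted_micro_in_range(self):
        s = simulate_stream(small_cfg(seed=1))
        assert np.all(np.diff(s.macro_ms) >= 0)
        assert s.micro_ns.min() >= 0
        assert s.micro_ns.max() < 25.0

    def test_channel_split_follows_efficiency(self):
        s = simulate_stream(small_cfg(seed=2, E=np.array([0.8])))
        red_frac = (s.channel == 1).mean()
        assert red_frac == pytest.approx(0.8, abs=0.01)

    def test_unstable_step_rejected(self):
        net = build_rate_matrix(2, {(0, 1): 50.0, (1, 0): 50.0})
        mix = MixtureModel(net=net, p_d=1.0, x_s=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="time step"):
            SimulationConfig(
                E=np.array([0.2, 0.8]), mixture=mix,
                det=DetectionModel(t_diff=1.5, Q0=100.0),
                duration_s=1.0, dt_us=5.0, seed=0)

    def test_mean_burst_E_matches_total_fractions(self, dilute_sim2_bursts):
        """Burst-averaged E agrees with the fraction-weighted mean."""
        x_total = 0.4 * np.array([0.5, 0.5, 0.0]) + 0.6 * np.full(3, 1 / 3)
        expected = mean_efficiency(x_total, [0.2, 0.5, 0.8])
        b = dilute_sim2_bursts
        se = b.E.std() / np.sqrt(len(b))
        # small bias from finite per-burst counts is tolerated via 4 sigma
        assert abs(b.E.mean() - expected) < max(4 * se, 0.02)


class TestDetectBursts:
    def test_empty_stream_warns_empty_table(self):
        s = PhotonStream(macro_ms=np.empty(0), channel=np.empty(0, dtype=np.uint8),
                         micro_ns=np.empty(0), duration_ms=10.0)
        with pytest.warns(UserWarning):
            b = detect_bursts(s)
        assert len(b) == 0

    def test_single_species_burst_E(self, static_single_stream):
        b = detect_bursts(static_single_stream)
        assert len(b) > 20
        assert b.E.mean() == pytest.approx(0.5, abs=0.02)
        assert np.all(b.n_green + b.n_red >= 60)

    def test_burst_lifetime_estimator(self, static_single_stream):
        b = detect_bursts(static_single_stream)
        # donor lifetime 2 ns; mean micro time ~ tau (wrap negligible)
        assert np.nanmean(b.tau_F_ns) == pytest.approx(2.0, abs=0.1)


class TestHistogram2d:
    def test_static_mass_on_static_line(self, static_single_stream):
        b = detect_bursts(static_single_stream)
        H, xe, ye = histogram2d(b, tau_D0=4.0, axes="lifetime")
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        ix, iy = np.unravel_index(np.argmax(H), H.shape)
        # mode near (tau = 2 ns, E = 0.5), i.e. on the static line
        assert xc[ix] == pytest.approx(2.0, abs=0.2)
        assert yc[iy] == pytest.approx(0.5, abs=0.05)

    def test_moment_and_variance_axes(self, static_single_stream):
        b = detect_bursts(static_single_stream)
        for axes in ("moment", "variance"):
            H, _, _ = histogram2d(b, tau_D0=4.0, axes=axes)
            assert H.sum() > 0

    def test_fast_exchange_mode_off_static_line(self, dilute_sim2_bursts):
        """Dynamic population sits at the equilibrium mix, above the line."""
        b = dilute_sim2_bursts
        off = b.E - (1.0 - b.tau_F_ns / 4.0)
        dyn = (off > 0.03) & (np.abs(b.E - 0.35) < 0.12)
        assert dyn.sum() > 100
        # mode position on the MF/LF dynamic line at x ~ 0.5: E ~ 0.35
        assert np.median(b.E[dyn]) == pytest.approx(0.35, abs=0.04)

    def test_empty_table_rejected(self):
        from fretkin.simulate import _empty_bursts

        with pytest.raises(ValueError):
            histogram2d(_empty_bursts(), tau_D0=4.0)


class TestTimeWindows:
    def test_static_width_scales_with_photon_count(self, static_single_stream):
        out = timewindow_histograms(static_single_stream, [0.5, 2.0],
                                    min_photons=30)
        stats = {}
        for T, (h, edges) in out.items():
            c = 0.5 * (edges[:-1] + edges[1:])
            m = (c * h).sum()
            stats[T] = np.sqrt(((c - m) ** 2 * h).sum())
        F_ratio = np.sqrt(
            window_counts(static_single_stream, 2.0, 30)[0].mean()
            / window_counts(static_single_stream, 0.5, 30)[0].mean())
        # widths shrink roughly as 1/sqrt(mean photons per window)
        assert stats[2.0] < stats[0.5]
        assert stats[0.5] / stats[2.0] == pytest.approx(F_ratio, rel=0.45)

    def test_burst_mode_windows_within_bursts(self, static_single_stream):
        b = detect_bursts(static_single_stream)
        F, NR = window_counts(static_single_stream, 0.5, min_photons=10,
                              bursts=b)
        assert len(F) > 0
        assert np.all(F >= 10)
        assert np.all(NR <= F)


def test_one_dimensional_histograms_degenerate_but_2d_differ():
    """A static 4-species mixture and the 3+dynamic mixture share the 1D
    efficiency histogram while the dynamic shift separates them in 2D."""
    from fretkin.fixtures import fixture_config

    b = {}
    for which in (1, 2):
        cfg = fixture_config(which, seed=6, duration_s=16.0, box_xy=16.0)
        b[which] = detect_bursts(simulate_stream(cfg))
    from scipy.stats import ks_2samp

    ks = ks_2samp(b[1].E, b[2].E).statistic
    assert ks < 0.12  # nearly indistinguishable 1D histograms
    off = {w: t.E - (1.0 - t.tau_F_ns / 4.0) for w, t in b.items()}
    frac_off = {w: (o > 0.05).mean() for w, o in off.items()}
    assert frac_off[2] > frac_off[1] + 0.1  # 2D separates them


def test_offline_fraction_increases_with_pd():
    """More dynamic molecules put more burst mass off the static line."""
    net = build_rate_matrix(2, {("MF", "LF"): 5.0, ("LF", "MF"): 5.0},
                            state_labels=("LF", "MF"))
    fracs = []
    for p_d in (0.2, 0.8):
        mix = MixtureModel(net=net, p_d=p_d, x_s=np.full(3, 1 / 3),
                           dynamic_states=(0, 1))
        cfg = SimulationConfig(
            E=np.array([0.2, 0.5, 0.8]), mixture=mix,
            det=DetectionModel(t_diff=5.0, Q0=500.0),
            n_molecules=30, duration_s=10.0, dt_us=10.0, seed=8, box_xy=12.0)
        b = detect_bursts(simulate_stream(cfg))
        off = b.E - (1.0 - b.tau_F_ns / 4.0)
        fracs.append((off > 0.05).mean())
    assert fracs[1] > fracs[0]
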