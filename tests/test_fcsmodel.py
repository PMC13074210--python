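"""Analytic color-FCS model functions and amplitude relations."""

import numpy as np
import pytest

from fretkin.fcsmodel import (
    DetectionModel,
    MixtureModel,
    amplitudes_from_indicators,
    color_fcs_curve,
    contrast_factors,
    diffusion_term,
    kinetic_amplitudes,
    kinetic_correlation,
    multitau_grid,
)
from fretkin.fretlines import FretIndicators
from fretkin.kinetics import build_rate_matrix, equilibrium_fractions


@pytest.fixture
def two_state_mix():
    net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
    return MixtureModel(net=net, p_d=0.4, x_s=np.array([0.3, 0.7]))


class TestDiffusionTerm:
    def test_unity_at_zero_lag(self):
        assert diffusion_term(0.0, 5.0, 0.25) == pytest.approx(1.0)

    def test_value_at_t_diff(self):
        assert diffusion_term(5.0, 5.0, 0.25) == pytest.approx(
            0.5 / np.sqrt(1.0625))

    def test_strictly_decreasing(self):
        t = multitau_grid()
        g = diffusion_term(t, 2.0, 0.25)
        assert np.all(np.diff(g) < 0)


class TestKineticCorrelation:
    def test_two_state_closed_form(self, two_state_mix):
        """Matrix-propagator route equals the two-state closed form."""
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.8, 0.2])
        t = multitau_grid()
        x = two_state_mix.x_total
        xd = equilibrium_fractions(two_state_mix.net)
        for S_a, S_b in [(qG, qG), (qG, qR), (qR, qR)]:
            d12 = contrast_factors(S_a, S_b, x)[0, 1]
            closed = 1.0 + d12 * (
                x[0] * (1 - x[0])
                + two_state_mix.p_d * xd[0] * (1 - xd[0]) * (np.exp(-4.0 * t) - 1)
            )
            G = kinetic_correlation(two_state_mix, S_a, S_b, t)
            assert np.abs(G - closed).max() < 1e-12

    def test_pure_dynamic_simplification(self):
        net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
        mix = MixtureModel(net=net, p_d=1.0, x_s=np.array([0.5, 0.5]))
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.8, 0.2])
        t = multitau_grid()
        xd = equilibrium_fractions(net)
        d12 = contrast_factors(qG, qR, mix.x_total)[0, 1]
        closed = 1.0 + d12 * xd[0] * (1 - xd[0]) * np.exp(-4.0 * t)
        G = kinetic_correlation(mix, qG, qR, t)
        assert np.abs(G - closed).max() < 1e-12

    def test_static_mixture_is_flat(self):
        net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
        mix = MixtureModel(net=net, p_d=0.0, x_s=np.array([0.4, 0.6]))
        det = DetectionModel()
        qG, _ = det.signal_vectors([0.8, 0.2])
        t = multitau_grid()
        G = kinetic_correlation(mix, qG, qG, t)
        assert np.ptp(G) < 1e-14
        A0, exps = kinetic_amplitudes(mix, qG, qG)
        assert exps == []
        assert G[0] == pytest.approx(1 + A0)

    def test_three_state_chain_two_exponentials(self):
        net = build_rate_matrix(
            3, {(0, 1): 5, (1, 0): 5, (1, 2): 5, (2, 1): 5})
        mix = MixtureModel(net=net, p_d=1.0, x_s=np.full(3, 1 / 3))
        det = DetectionModel()
        # asymmetric efficiencies so both kinetic modes couple (for
        # equally spaced E the fast mode's GR amplitude vanishes by symmetry)
        qG, qR = det.signal_vectors([0.2, 0.45, 0.8])
        A0, exps = kinetic_amplitudes(mix, qG, qR)
        lam = sorted(l for l, _ in exps)
        assert np.allclose(lam, [-15.0, -5.0])  # 66.7 and 200 us

    def test_amplitude_expansion_matches_direct(self, two_state_mix):
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.8, 0.2])
        t = multitau_grid()
        A0, exps = kinetic_amplitudes(two_state_mix, qG, qR)
        series = 1.0 + A0 + sum(A * np.exp(l * t) for l, A in exps)
        direct = kinetic_correlation(two_state_mix, qG, qR, t)
        assert np.abs(series - direct).max() < 1e-12

    def test_long_time_plateau_is_static_residual(self, two_state_mix):
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.8, 0.2])
        A0, _ = kinetic_amplitudes(two_state_mix, qG, qR)
        G_inf = kinetic_correlation(two_state_mix, qG, qR, np.array([1e4]))
        assert G_inf[0] == pytest.approx(1 + A0, abs=1e-12)

    def test_zero_mean_signal_is_error(self, two_state_mix):
        with pytest.raises(ValueError, match="mean signal"):
            kinetic_correlation(
                two_state_mix, np.zeros(2), np.ones(2), np.array([0.1]))


class TestContrastFactors:
    def test_hand_computed_values(self):
        det = DetectionModel()
        E = np.array([0.8, 0.2])
        x = np.array([0.5, 0.5])
        qG, qR = det.signal_vectors(E)
        assert contrast_factors(qG, qG, x)[0, 1] == pytest.approx(1.44)
        assert contrast_factors(qR, qR, x)[0, 1] == pytest.approx(1.44)
        assert contrast_factors(qG, qR, x)[0, 1] == pytest.approx(-1.44)

    def test_identical_species_zero_contrast(self):
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.5, 0.5])
        assert np.allclose(contrast_factors(qG, qR, [0.5, 0.5]), 0.0)

    def test_cross_amplitude_identity(self):
        """The GR amplitude is minus the geometric mean of GG and RR."""
        det = DetectionModel()
        qG, qR = det.signal_vectors([0.7, 0.3])
        x = np.array([0.6, 0.4])
        dGG = contrast_factors(qG, qG, x)[0, 1]
        dRR = contrast_factors(qR, qR, x)[0, 1]
        dGR = contrast_factors(qG, qR, x)[0, 1]
        assert dGR == pytest.approx(-np.sqrt(dGG * dRR), abs=1e-12)


class TestColorFcsCurve:
    def test_single_species_reduces_to_diffusion(self):
        net = build_rate_matrix(2, {(1, 0): 1.0, (0, 1): 1.0})
        mix = MixtureModel(net=net, p_d=0.0, x_s=np.array([1.0, 0.0]))
        det = DetectionModel(t_diff=5.0, N_mol=2.0)
        c = color_fcs_curve(mix, det, [0.5, 0.5], "GG")
        expected = 1.0 + diffusion_term(c.lag, 5.0, det.s) / 2.0
        assert np.allclose(c.G, expected, atol=1e-12)

    def test_cross_correlation_anticorrelated_dip(self):
        net = build_rate_matrix(2, {(1, 0): 5.0, (0, 1): 5.0})
        mix = MixtureModel(net=net, p_d=1.0, x_s=np.array([0.5, 0.5]))
        det = DetectionModel(t_diff=5.0, N_mol=1.0)
        c = color_fcs_curve(mix, det, [0.8, 0.2], "GR")
        # rises with lag below ~t_R (anti-correlated kinetic term)
        short = c.G[c.lag < 0.05]
        assert np.all(np.diff(short) > 0)
        A0, exps = kinetic_amplitudes(
            mix, *det.signal_vectors([0.8, 0.2]))
        assert exps[0][0] == pytest.approx(-10.0)  # 100 us relaxation

    def test_long_time_limit_is_one(self, subtests=None):
        net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
        mix = MixtureModel(net=net, p_d=0.4, x_s=np.array([0.5, 0.5]))
        det = DetectionModel(t_diff=2.0)
        for pair in ("GG", "GR", "RG", "RR"):
            c = color_fcs_curve(mix, det, [0.8, 0.2], pair,
                                t_c=np.array([1e5, 2e5]))
            assert np.allclose(c.G, 1.0, atol=1e-6)


class TestAmbiguityManifold:
    def test_matched_triples_give_identical_curves(self):
        """(p_d, k12, k21) families with equal t_R, p_d xd1 xd2 and x_total
        produce kinetic correlations identical to numerical precision."""
        det = DetectionModel()
        E = [0.2, 0.5, 0.8]
        qG, qR = det.signal_vectors(E)
        t = multitau_grid()
        k = 10.0  # fixed relaxation rate
        ref = None
        # reference mixture: p_d=0.4, symmetric rates
        p_ref, x1_ref = 0.4, 0.5
        amp = p_ref * x1_ref * (1 - x1_ref)
        x_total_ref = None
        for p_d in (0.4, 0.45, 0.5):
            q = amp / p_d
            x1 = 0.5 * (1 + np.sqrt(1 - 4 * q))
            net = build_rate_matrix(2, {(1, 0): x1 * k, (0, 1): (1 - x1) * k})
            if x_total_ref is None:
                xs = np.array([0.3, 0.3, 0.4])
                mix = MixtureModel(net=net, p_d=p_d, x_s=xs,
                                   dynamic_states=(0, 1))
                x_total_ref = mix.x_total
            else:
                xd = np.zeros(3)
                xd[[0, 1]] = [x1, 1 - x1]
                xs = (x_total_ref - p_d * xd) / (1 - p_d)
                assert np.all(xs > -1e-12)
                mix = MixtureModel(net=net, p_d=p_d, x_s=np.clip(xs, 0, None),
                                   dynamic_states=(0, 1))
            G = kinetic_correlation(mix, qG, qR, t)
            if ref is None:
                ref = G
            else:
                assert np.abs(G - ref).max() < 1e-10


class TestAmplitudesFromIndicators:
    def test_static_burst_zero(self):
        ind = FretIndicators(E=0.4, tau_F=4.0 * 0.6, tau_D0=4.0)
        assert amplitudes_from_indicators(ind) == pytest.approx((0, 0, 0))

    def test_binary_mixture_example(self):
        ind = FretIndicators(E=0.5, tau_F=2.72, tau_D0=4.0)
        gg, rr, gr = amplitudes_from_indicators(ind)
        assert gg == pytest.approx(0.36)
        assert rr == pytest.approx(0.36)
        assert gr == pytest.approx(-0.36)
        assert gr**2 == pytest.approx(gg * rr)

    def test_extreme_efficiency_raises(self):
        with pytest.raises(ZeroDivisionError):
            amplitudes_from_indicators(
                FretIndicators(E=1.0, tau_F=0.0, tau_D0=4.0))


def test_multitau_grid_strictly_increasing():
    g = multitau_grid()
    assert np.all(np.diff(g) > 0)
    assert g[0] == pytest.approx(1e-4)
    assert g[-1] <= 100.0


def test_curve_io_roundtrip(tmp_path):
    from fretkin.fcsmodel import CorrelationCurve
    from fretkin.io import read_curve, write_curve

    c = CorrelationCurve(lag=np.array([0.1, 0.2, 0.4]),
                         G=np.array([1.5, 1.2, 1.1]),
                         sigma=np.array([0.01, 0.02, 0.03]), pair="GR")
    path = tmp_path / "c.tsv"
    write_curve(path, c)
    back = read_curve(path)
    assert back.pair == "GR"
    assert np.allclose(back.lag, c.lag)
    assert np.allclose(back.G, c.G)
    assert np.allclose(back.sigma, c.sigma)
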