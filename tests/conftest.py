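"""Shared simulated datasets (session-scoped: simulations are expensive)."""

import numpy as np
import pytest

from fretkin.correlate import correlate_photons
from fretkin.fcsmodel import DetectionModel, MixtureModel
from fretkin.kinetics import build_rate_matrix
from fretkin.simulate import SimulationConfig, detect_bursts, simulate_stream
from fretkin.tcspc import subensemble_decay

SPECIES_E = np.array([0.2, 0.5, 0.8])  # LF, MF, HF
TAU_D0 = 4.0


def sim2_mixture():
    """Three static species + dynamic MF <-> LF at 5/5 ms^-1, p_d = 0.4."""
    net = build_rate_matrix(2, {("MF", "LF"): 5.0, ("LF", "MF"): 5.0},
                            state_labels=("LF", "MF"))
    return MixtureModel(net=net, p_d=0.4, x_s=np.full(3, 1 / 3),
                        dynamic_states=(0, 1))


@pytest.fixture(scope="session")
def sim2_stream():
    """FCS-grade stream of the two-state MF<->LF mixture (concentrated)."""
    cfg = SimulationConfig(
        E=SPECIES_E, mixture=sim2_mixture(),
        det=DetectionModel(t_diff=5.0, Q0=500.0),
        n_molecules=30, duration_s=45.0, dt_us=10.0, seed=31,
    )
    return simulate_stream(cfg)


@pytest.fixture(scope="session")
def sim2_global_data(sim2_stream):
    from fretkin.globalfit import GlobalData

    s = sim2_stream
    decay = subensemble_decay(s, n_bins=512)
    g = s.macro_ms[s.channel == 0]
    r = s.macro_ms[s.channel == 1]
    curves = {
        p: correlate_photons(a, b, s.duration_ms, bin_ms=0.005, pair=p)
        for p, (a, b) in
        {"GG": (g, g), "GR": (g, r), "RG": (r, g), "RR": (r, r)}.items()
    }
    return GlobalData(decay=decay, curves=curves, tau_D0=TAU_D0,
                      lag_max_ms=20.0)


@pytest.fixture(scope="session")
def sim2_scheme_fits(sim2_global_data):
    """Global fits of all three dynamic-pair assignments."""
    from fretkin.globalfit import GlobalModel, fit_global

    pairs = tuple(sim2_global_data.curves)
    out = {}
    for scheme in [(0, 1), (0, 2), (1, 2)]:
        model = GlobalModel(
            n_species=3, scheme=scheme,
            values={"E1": 0.25, "E2": 0.5, "E3": 0.75, "k12": 3.0,
                    "k21": 3.0, "xs1": 0.33, "xs2": 0.33, "p_d": 0.5,
                    "t_diff": 4.0, "N": 2.5},
            offset_pairs=pairs, scale_pairs=pairs,
            bounds={"E1": (0.05, 0.35), "E2": (0.35, 0.65),
                    "E3": (0.65, 0.95)},
        )
        out[scheme] = fit_global(sim2_global_data, model, n_starts=5, seed=1)
    return out


@pytest.fixture(scope="session")
def dilute_sim2_stream():
    """Burst-grade (dilute) stream of the same mixture, for PDA/workflow."""
    cfg = SimulationConfig(
        E=SPECIES_E, mixture=sim2_mixture(),
        det=DetectionModel(t_diff=5.0, Q0=500.0),
        n_molecules=30, duration_s=80.0, dt_us=10.0, seed=41, box_xy=16.0,
    )
    return simulate_stream(cfg)


@pytest.fixture(scope="session")
def dilute_sim2_bursts(dilute_sim2_stream):
    return detect_bursts(dilute_sim2_stream)


@pytest.fixture(scope="session")
def binary_ffcs_case():
    """Binary HF <-> LF exchange with static background (fFCS reference)."""
    net = build_rate_matrix(2, {("HF", "LF"): 5.0, ("LF", "HF"): 5.0},
                            state_labels=("LF", "HF"))
    mix = MixtureModel(net=net, p_d=0.4, x_s=np.full(3, 1 / 3),
                       dynamic_states=(0, 2))
    cfg = SimulationConfig(
        E=SPECIES_E, mixture=mix,
        det=DetectionModel(t_diff=3.8, Q0=500.0),
        n_molecules=30, duration_s=20.0, dt_us=10.0, seed=11,
    )
    return simulate_stream(cfg), mix


def _chain_stream(order, seed):
    a, b, c = order
    net = build_rate_matrix(
        3, {(a, b): 5.0, (b, a): 5.0, (b, c): 5.0, (c, b): 5.0},
        state_labels=order)
    labels = ("LF", "MF", "HF")
    dyn = tuple(labels.index(x) for x in order)
    mix = MixtureModel(net=net, p_d=0.4, x_s=np.full(3, 1 / 3),
                       dynamic_states=dyn)
    cfg = SimulationConfig(
        E=SPECIES_E, mixture=mix,
        det=DetectionModel(t_diff=3.8, Q0=500.0),
        n_molecules=30, duration_s=20.0, dt_us=5.0, seed=seed,
    )
    return simulate_stream(cfg), mix, order


@pytest.fixture(scope="session")
def chain_streams():
    """The three linear-chain topologies at 5 ms^-1 everywhere."""
    return [
        _chain_stream(("MF", "HF", "LF"), 21),
        _chain_stream(("HF", "MF", "LF"), 22),
        _chain_stream(("MF", "LF", "HF"), 23),
    ]


@pytest.fixture(scope="session")
def static_single_stream():
    """One static species at E = 0.5 (estimator sanity checks)."""
    cfg = SimulationConfig(
        E=np.array([0.5]), mixture=None, x_s=np.array([1.0]),
        det=DetectionModel(t_diff=1.5, Q0=300.0),
        n_molecules=20, duration_s=10.0, dt_us=5.0, seed=5, box_xy=10.0,
    )
    return simulate_stream(cfg)
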