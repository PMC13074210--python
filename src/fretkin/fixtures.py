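"""Canonical synthetic experiments: seven reference simulations.

These configurations regenerate the study's reference scenarios for
three-state systems (species LF, MF, HF at E = 0.2, 0.5, 0.8; donor-only
lifetime 4 ns; no linker dynamics):

1. four static species (LF, MF, MF', HF) — purely static control;
2. three static species + dynamic MF <-> LF, 5/5 ms^-1;
3. three static species + dynamic HF <-> LF, 6.3/3.7 ms^-1;
4. three static species + dynamic HF <-> LF, 5/5 ms^-1 (binary reference
   for filtered-FCS);
5. linear chain MF <-> HF <-> LF, all rates 5 ms^-1;
6. linear chain HF <-> MF <-> LF, all rates 5 ms^-1;
7. linear chain MF <-> LF <-> HF, all rates 5 ms^-1 (relaxation times
   67 and 200 us).

Diffusion times: 5 ms for simulations 1-3 and 3.8 ms for 4-7.  The
static background holds equal fractions of the three main species and the
dynamic-molecule fraction is 0.4; brightness and box settings are chosen
for ideal single-molecule statistics.  Each simulation is deterministic
under a fixed seed; a manifest of all parameters is written next to the
outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .fcsmodel import DetectionModel, MixtureModel
from .kinetics import build_rate_matrix
from .simulate import SimulationConfig, detect_bursts, simulate_stream

__all__ = ["fixture_config", "make_fixtures", "SPECIES_E", "SPECIES_LABELS"]

SPECIES_LABELS = ("LF", "MF", "HF")
SPECIES_E = {"LF": 0.2, "MF": 0.5, "HF": 0.8, "MFp": 0.35}
TAU_D0_NS = 4.0
P_DYNAMIC = 0.4
Q0_KHZ = 500.0
N_MOLECULES = 30

_CHAINS = {
    5: ("MF", "HF", "LF"),
    6: ("HF", "MF", "LF"),
    7: ("MF", "LF", "HF"),
}


def fixture_config(
    which: int,
    seed: int = 0,
    duration_s: float = 20.0,
    n_molecules: int = N_MOLECULES,
    box_xy: float = 4.0,
) -> SimulationConfig:
    """Simulation configuration of reference simulation 1..7."""
    if which == 1:
        E = [SPECIES_E["LF"], SPECIES_E["MFp"], SPECIES_E["MF"], SPECIES_E["HF"]]
        det = DetectionModel(t_diff=5.0, Q0=Q0_KHZ)
        # MF' carries the weight of simulation 2's dynamic population so the
        # 1D efficiency histograms of simulations 1 and 2 coincide
        return SimulationConfig(
            E=np.array(E), mixture=None, x_s=np.array([0.2, 0.4, 0.2, 0.2]),
            det=det,
            tau_D0=TAU_D0_NS, n_molecules=n_molecules,
            duration_s=duration_s, dt_us=10.0, seed=seed,
            labels=("LF", "MFp", "MF", "HF"), box_xy=box_xy,
        )
    E = np.array([SPECIES_E[l] for l in SPECIES_LABELS])
    x_s = np.full(3, 1.0 / 3.0)
    if which == 2:
        net = build_rate_matrix(2, {("MF", "LF"): 5.0, ("LF", "MF"): 5.0},
                                state_labels=("LF", "MF"))
        dyn = (0, 1)
        det = DetectionModel(t_diff=5.0, Q0=Q0_KHZ)
        dt = 10.0
    elif which == 3:
        net = build_rate_matrix(2, {("HF", "LF"): 6.3, ("LF", "HF"): 3.7},
                                state_labels=("LF", "HF"))
        dyn = (0, 2)
        det = DetectionModel(t_diff=5.0, Q0=Q0_KHZ)
        dt = 10.0
    elif which == 4:
        net = build_rate_matrix(2, {("HF", "LF"): 5.0, ("LF", "HF"): 5.0},
                                state_labels=("LF", "HF"))
        dyn = (0, 2)
        det = DetectionModel(t_diff=3.8, Q0=Q0_KHZ)
        dt = 10.0
    elif which in _CHAINS:
        a, b, c = _CHAINS[which]
        net = build_rate_matrix(
            3,
            {(a, b): 5.0, (b, a): 5.0, (b, c): 5.0, (c, b): 5.0},
            state_labels=(a, b, c),
        )
        dyn = tuple(SPECIES_LABELS.index(l) for l in (a, b, c))
        det = DetectionModel(t_diff=3.8, Q0=Q0_KHZ)
        dt = 5.0
    else:
        raise ValueError("fixture index must be 1..7")
    mix = MixtureModel(net=net, p_d=P_DYNAMIC, x_s=x_s, dynamic_states=dyn)
    return SimulationConfig(
        E=E, mixture=mix, det=det, tau_D0=TAU_D0_NS,
        n_molecules=n_molecules, duration_s=duration_s, dt_us=dt,
        seed=seed, labels=SPECIES_LABELS, box_xy=box_xy,
    )


def _manifest(cfg: SimulationConfig, which: int) -> dict:
    man = {
        "simulation": which,
        "E_species": [float(e) for e in cfg.E],
        "labels": list(cfg.labels),
        "tau_D0_ns": cfg.tau_D0,
        "t_diff_ms": cfg.det.t_diff,
        "Q0_kHz": cfg.det.Q0,
        "n_molecules": cfg.n_molecules,
        "duration_s": cfg.duration_s,
        "dt_us": cfg.dt_us,
        "seed": cfg.seed,
        "p_d": cfg.p_d,
        "x_static": [float(x) for x in cfg.x_static],
    }
    if cfg.mixture is not None:
        from .io import network_to_config

        man["network"] = network_to_config(cfg.mixture.net)
        man["dynamic_states"] = list(cfg.mixture.dynamic_states)
    return man


def make_fixtures(which, seed: int = 0, outdir=None, duration_s: float = 20.0):
    """Simulate reference experiments and (optionally) write artifacts.

    ``which`` is an index or iterable of indices in 1..7.  Returns
    ``{index: (stream, bursts, manifest)}``; with ``outdir`` set, writes
    ``simN_bursts.tsv`` and ``simN_manifest.yaml`` per simulation (the raw
    photon stream is kept in memory — export it explicitly if needed).
    """
    from .io import write_bursts

    if np.isscalar(which):
        which = [int(which)]
    out = {}
    for w in which:
        cfg = fixture_config(int(w), seed=seed, duration_s=duration_s)
        stream = simulate_stream(cfg)
        bursts = detect_bursts(stream)
        man = _manifest(cfg, int(w))
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_bursts(outdir / f"sim{w}_bursts.tsv", bursts)
            (outdir / f"sim{w}_manifest.yaml").write_text(yaml.safe_dump(man))
        out[int(w)] = (stream, bursts, man)
    return out
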