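"""Three-step analysis workflow for multi-state kinetics.

Step 1 (model selection): burst histogram + FRET-lines locate static and
dynamic populations; color-FCS counts relaxation times; the sub-ensemble
donor decay counts exchanging species; candidate binary schemes are
admitted or eliminated by whether the dynamic population sits on the
corresponding binary dynamic FRET-line.

Step 2 (quantification): relaxation time from the green-red
cross-correlation; the dynamic fraction of the exchanging pair read off
the dynamic-line position; microscopic rates from (t_R, x_d); optionally a
dynamic-PDA fit for p_d.

Step 3 (validation): re-simulate with the inferred model and compare the
FRET-efficiency histograms (Kolmogorov-Smirnov distance).

Every candidate scheme in the report carries the evidence that admitted
or eliminated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlate import correlate_photons
from .fcsfit import fit_correlation
from .fretlines import _mixture_indicators
from .simulate import BurstTable, PhotonStream, detect_bursts

__all__ = ["WorkflowConfig", "WorkflowReport", "run_workflow"]


@dataclass
class WorkflowConfig:
    tau_D0: float = 4.0
    t_diff_hint: float = 5.0
    ds_threshold: float = 0.03  # vertical offset above which a burst is "dynamic"
    line_tolerance: float = 0.05  # admissible distance from a binary line
    min_peak_fraction: float = 0.05
    pda_windows: tuple = ()  # e.g. (1.0, 2.0, 3.0) ms to enable PDA
    validate: bool = False  # step 3 re-simulation
    seed: int = 0


@dataclass
class WorkflowReport:
    static_species_E: list
    dynamic_population: dict  # mode E, mode tau, vertical offset, fraction
    n_relaxations: int
    relaxation_times_ms: list
    n_decay_components: int
    candidate_schemes: list  # dicts with pair, admitted, evidence
    selected_scheme: tuple | None
    rates: dict = field(default_factory=dict)
    pda: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def has_dynamics(self) -> bool:
        return self.n_relaxations > 0 and self.dynamic_population["fraction"] > 0


def _find_static_peaks(E_vals, min_fraction):
    """Peak efficiencies of the on-line (static) burst population."""
    h, edges = np.histogram(E_vals, bins=50, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sm = np.convolve(h, np.ones(3) / 3.0, mode="same")
    from scipy.signal import find_peaks

    pk, _ = find_peaks(sm, prominence=min_fraction * max(len(E_vals), 1) * 0.02)
    return [float(centers[i]) for i in pk]


def _line_offset(E_pop, tau_pop, E1, E2, tau_D0):
    """Distance of a population from the (E1,E2) binary dynamic line.

    Evaluates the dynamic line at the population's efficiency (occupancy
    solved from E) and returns |tau_line - tau_pop| / tau_D0, or None when
    the efficiency lies outside [min(E1,E2), max(E1,E2)].
    """
    lo, hi = min(E1, E2), max(E1, E2)
    if not lo - 1e-9 <= E_pop <= hi + 1e-9:
        return None
    x = (E_pop - E2) / (E1 - E2)
    _, tau_line = _mixture_indicators(np.array([x]), E1, E2, tau_D0)
    return float(abs(tau_line[0] - tau_pop) / tau_D0)


def run_workflow(
    stream: PhotonStream,
    cfg: WorkflowConfig,
    bursts: BurstTable | None = None,
) -> WorkflowReport:
    if bursts is None:
        bursts = detect_bursts(stream)
    if len(bursts) == 0:
        raise ValueError("no bursts detected; cannot run the workflow")
    tau_D0 = cfg.tau_D0
    E_tau_line = 1.0 - bursts.tau_F_ns / tau_D0  # E of the static line
    offset = bursts.E - E_tau_line  # vertical offset from static line
    dyn_mask = offset > cfg.ds_threshold

    # --- step 1.1: populations on/off the static line
    static_E = _find_static_peaks(bursts.E[~dyn_mask], cfg.min_peak_fraction)
    dyn_frac = float(dyn_mask.mean())
    if dyn_mask.sum() >= 10:
        hE, eE = np.histogram(bursts.E[dyn_mask], bins=40, range=(0, 1))
        Em = float(0.5 * (eE[np.argmax(hE)] + eE[np.argmax(hE) + 1]))
        tau_m = float(np.median(bursts.tau_F_ns[dyn_mask]))
        dsm = float(np.median(offset[dyn_mask]))
    else:
        Em, tau_m, dsm = float("nan"), float("nan"), 0.0
    dynamic_population = {
        "mode_E": Em, "median_tau_F_ns": tau_m,
        "median_offset": dsm, "fraction": dyn_frac,
    }

    # --- step 1.2: color-FCS relaxation count
    g = stream.macro_ms[stream.channel == 0]
    r = stream.macro_ms[stream.channel == 1]
    cgr = correlate_photons(g, r, stream.duration_ms, bin_ms=0.005, pair="GR")
    fits = {}
    for n_rel in (0, 1, 2):
        fits[n_rel] = fit_correlation(
            cgr, n_relaxations=n_rel, t_diff_init=cfg.t_diff_hint,
            lag_min=0.008, lag_max=4 * cfg.t_diff_hint,
        )
    n_relax = 0
    for n_rel in (1, 2):
        if fits[n_rel].redchi < 0.8 * fits[n_relax].redchi:
            n_relax = n_rel
    t_R = list(fits[n_relax].t_R) if n_relax else []

    # --- step 1.3: sub-ensemble decay of the dynamic population
    from .tcspc import fit_decay, subensemble_decay

    n_comp = 0
    if dyn_mask.sum() >= 10:
        sed = subensemble_decay(stream, bursts=bursts, mask=dyn_mask, n_bins=256)
        prev = None
        for n in (1, 2, 3):
            fit = fit_decay(sed, n, tau_D0)
            if prev is not None and fit.redchi > 0.8 * prev:
                break
            n_comp = n
            prev = fit.redchi

    # --- step 1.4: candidate schemes against binary dynamic lines
    candidates = []
    selected = None
    notes = []
    if dyn_frac > 0.01 and len(static_E) >= 2 and np.isfinite(Em):
        from itertools import combinations

        admitted = []
        for i, j in combinations(range(len(static_E)), 2):
            E1, E2 = static_E[i], static_E[j]
            d = _line_offset(Em, tau_m, E1, E2, tau_D0)
            ok = d is not None and d < cfg.line_tolerance
            why = (
                "dynamic population outside the efficiency range"
                if d is None
                else f"distance to line {d:.3f} "
                + ("<" if ok else ">=")
                + f" {cfg.line_tolerance}"
            )
            candidates.append({"pair": (E1, E2), "admitted": ok, "evidence": why})
            if ok:
                admitted.append((i, j, d))
        if len(admitted) == 1:
            selected = tuple(admitted[0][:2])
        elif len(admitted) > 1:
            admitted.sort(key=lambda t: t[2])
            selected = tuple(admitted[0][:2])
            notes.append("multiple admissible schemes; nearest line selected")
        elif n_relax >= 1:
            notes.append(
                "dynamic population between limiting binary lines: "
                ">= 3-state exchange indicated; route to filtered-FCS"
            )
    elif dyn_frac <= 0.01:
        notes.append("no dynamic population: all mass on the static line")
    if n_relax == 0:
        notes.append(
            "no FCS relaxation: static mixture on sub-diffusion timescales")

    # --- step 2: quantification for the selected scheme
    rates = {}
    if selected is not None and n_relax >= 1:
        E1, E2 = static_E[selected[0]], static_E[selected[1]]
        x_d1 = float(np.clip((Em - E2) / (E1 - E2), 0.0, 1.0))
        tR = t_R[0]
        rates = {
            "t_R_ms": tR,
            "x_d1": x_d1,
            "k12_ms": x_d1 / tR,
            "k21_ms": (1.0 - x_d1) / tR,
            "p_d_offline": dyn_frac,
        }

    pda_out = {}
    if cfg.pda_windows and selected is not None:
        from .pda import PdaDataset, fit_pda
        from .simulate import window_counts

        E_all = list(static_E)
        datasets = []
        for T in cfg.pda_windows:
            F, NR = window_counts(stream, T, min_photons=20)
            if len(F) > 50:
                datasets.append(PdaDataset(T_ms=T, F=F, n_red=NR))
        if datasets:
            out = fit_pda(datasets, E_all, dynamic_pair=selected,
                          n_starts=4, seed=cfg.seed)
            pda_out = {k: out[k] for k in ("p_d", "k12", "k21", "chi2_r")}

    # --- step 3: validation by re-simulation
    validation = {}
    if cfg.validate and selected is not None and rates:
        from .fcsmodel import DetectionModel, MixtureModel
        from .kinetics import build_rate_matrix
        from .simulate import SimulationConfig, simulate_stream

        E_stat = np.array(static_E)
        net = build_rate_matrix(
            2, {(1, 0): rates["k12_ms"], (0, 1): rates["k21_ms"]}
        )
        x_s = np.full(len(E_stat), 1.0 / len(E_stat))
        mix = MixtureModel(net=net, p_d=min(max(dyn_frac, 0.05), 0.95),
                           x_s=x_s, dynamic_states=selected)
        det = DetectionModel(t_diff=cfg.t_diff_hint, Q0=300.0)
        cfg2 = SimulationConfig(
            E=E_stat, mixture=mix, det=det, tau_D0=tau_D0,
            n_molecules=20, duration_s=min(stream.duration_ms / 1e3, 10.0),
            dt_us=min(10.0, 100.0 / (rates["k12_ms"] + rates["k21_ms"])),
            seed=cfg.seed + 1,
        )
        sim = simulate_stream(cfg2)
        b2 = detect_bursts(sim)
        if len(b2):
            from scipy.stats import ks_2samp

            ks = ks_2samp(bursts.E, b2.E)
            validation = {"ks_distance": float(ks.statistic),
                          "ks_pvalue": float(ks.pvalue)}

    return WorkflowReport(
        static_species_E=static_E,
        dynamic_population=dynamic_population,
        n_relaxations=n_relax,
        relaxation_times_ms=t_R,
        n_decay_components=n_comp,
        candidate_schemes=candidates,
        selected_scheme=selected,
        rates=rates,
        pda=pda_out,
        validation=validation,
        notes=notes,
    )
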