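"""Photon-level Monte Carlo simulation of diffusion-based smFRET experiments.

Molecules perform free Brownian motion in a periodic box around a 3D
Gaussian observation volume W(r) = exp(-2(x^2+y^2)/w0^2 - 2 z^2/z0^2);
the diffusion coefficient is chosen so that the mean dwell time obeys
t_diff = w0^2 / (4 D).  A fraction p_d of molecules carries a
continuous-time Markov chain over the conformational states (exact
exponential waiting times, so relaxation times are unbiased by the
diffusion time step); the rest keep a fixed state drawn from the static
fractions.  Photons are emitted as an inhomogeneous Poisson process with
rate Q0 W(r(t)), split between the green (donor) and red (acceptor)
detection channels by the instantaneous FRET efficiency (with gamma and
alpha corrections), and carry micro times drawn from the corresponding
fluorescence decay: exponential with tau_D0 (1 - E_state) for donor
photons and with the acceptor lifetime for red photons.

Length unit: the focal waist w0.  Times: macro in ms, micro in ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcsmodel import DetectionModel, MixtureModel
from .kinetics import eigen_decompose, equilibrium_fractions

__all__ = [
    "SimulationConfig",
    "PhotonStream",
    "BurstTable",
    "simulate_stream",
    "detect_bursts",
    "histogram2d",
    "timewindow_histograms",
    "window_counts",
]

#: box side lengths in units of (w0, w0, z0)
BOX_XY = 4.0
BOX_Z = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated smFRET experiment."""

    E: np.ndarray  # species FRET efficiencies
    mixture: MixtureModel | None  # None -> fully static mixture x_s
    det: DetectionModel
    x_s: np.ndarray | None = None  # static fractions if mixture is None
    tau_D0: float = 4.0  # ns
    tau_A: float = 1.0  # ns, acceptor fluorescence lifetime
    n_molecules: int = 20
    duration_s: float = 10.0
    dt_us: float = 2.0
    micro_range_ns: float = 25.0
    seed: int = 0
    labels: tuple = field(default=())
    box_xy: float = BOX_XY  # box side in units of w0
    box_z: float = BOX_Z  # box height in units of z0

    def __post_init__(self):
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if self.mixture is None and self.x_s is None:
            raise ValueError("need a MixtureModel or static fractions x_s")
        dt_ms = self.dt_us * 1e-3
        lim = self.det.t_diff
        if self.mixture is not None and self.mixture.p_d > 0:
            lam = eigen_decompose(self.mixture.net).eigenvalues
            if len(lam) > 1:
                lim = min(lim, float(1.0 / np.abs(lam[1:]).max()))
        if dt_ms > lim / 10.0 + 1e-12:
            raise ValueError(
                f"time step {self.dt_us} us too coarse: must be <= "
                f"min(relaxation time, t_diff)/10 = {lim / 10 * 1e3:.3g} us"
            )

    @property
    def x_static(self) -> np.ndarray:
        if self.mixture is not None:
            return self.mixture.x_s
        return np.asarray(self.x_s, dtype=float)

    @property
    def p_d(self) -> float:
        return self.mixture.p_d if self.mixture is not None else 0.0


@dataclass
class PhotonStream:
    """Time-ordered photon records of a simulated (or loaded) measurement."""

    macro_ms: np.ndarray  # nondecreasing arrival times
    channel: np.ndarray  # uint8: 0 = green/donor, 1 = red/acceptor
    micro_ns: np.ndarray  # TCSPC micro time
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.macro_ms = np.asarray(self.macro_ms, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.micro_ns = np.asarray(self.micro_ns, dtype=np.float32)
        if np.any(np.diff(self.macro_ms) < 0):
            raise ValueError("macro times must be nondecreasing")

    def __len__(self):
        return len(self.macro_ms)


@dataclass
class BurstTable:
    """Per-burst summary quantities from a sliding-window burst search."""

    start_ms: np.ndarray
    stop_ms: np.ndarray
    n_green: np.ndarray
    n_red: np.ndarray
    E: np.ndarray  # N_R / (N_G + N_R), ideal gamma=1, alpha=0
    tau_F_ns: np.ndarray  # mean donor micro time
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.start_ms)

    @property
    def duration_ms(self) -> np.ndarray:
        return self.stop_ms - self.start_ms

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start_ms": self.start_ms,
                "stop_ms": self.stop_ms,
                "n_green": self.n_green,
                "n_red": self.n_red,
                "E": self.E,
                "tau_F_ns": self.tau_F_ns,
            }
        )


def _largest_remainder(fracs, n: int) -> np.ndarray:
    """Integer apportionment of ``n`` items to ``fracs`` (sums to n)."""
    fracs = np.asarray(fracs, dtype=float)
    raw = fracs * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:rem]] += 1
    return base


def _gillespie_trajectory(rng, K: np.ndarray, x0_probs, duration_ms: float):
    """Jump times and states of one CTMC realization on [0, duration].

    Returns (times, states): ``states[k]`` holds from ``times[k]`` to
    ``times[k+1]`` (times[0] = 0).
    """
    n = K.shape[0]
    escape = -np.diag(K)
    s0 = int(np.searchsorted(np.cumsum(x0_probs), rng.random(), side="right"))
    s0 = min(s0, n - 1)

    if n == 2 and escape.min() > 0:
        # two states alternate deterministically: draw all waits en bloc
        n_est = int(duration_ms * escape.max() * 1.3) + 32
        while True:
            waits = rng.exponential(1.0, size=n_est)
            states = (s0 + np.arange(n_est)) % 2
            dt_j = waits / escape[states]
            times = np.concatenate(([0.0], np.cumsum(dt_j)))
            if times[-1] >= duration_ms:
                break
            n_est *= 2  # pragma: no cover - generous initial estimate
        last = int(np.searchsorted(times, duration_ms))
        return times[:last], states[: max(last, 1)].astype(np.int8)

    # generic embedded chain: python loop with plain-float branching
    cum_rows = []
    for j in range(n):
        p = K[:, j].copy()
        p[j] = 0.0
        tot = p.sum()
        cum_rows.append(
            tuple(np.cumsum(p / tot)) if tot > 0 else tuple(np.ones(n))
        )
    esc = tuple(float(e) for e in escape)
    times = [0.0]
    states = [s0]
    s = s0
    t = 0.0
    block = 8192
    waits = rng.exponential(1.0, size=block)
    us = rng.random(block)
    i = 0
    while esc[s] > 0:
        if i >= block:
            waits = rng.exponential(1.0, size=block)
            us = rng.random(block)
            i = 0
        t += waits[i] / esc[s]
        if t >= duration_ms:
            break
        u = us[i]
        row = cum_rows[s]
        nxt = 0
        while nxt < n - 1 and u >= row[nxt]:
            nxt += 1
        s = nxt
        states.append(s)
        times.append(t)
        i += 1
    return np.asarray(times), np.asarray(states, dtype=np.int8)


def simulate_stream(cfg: SimulationConfig) -> PhotonStream:
    """Run the Monte Carlo and return the time-ordered photon stream."""
    rng = np.random.default_rng(cfg.seed)
    det = cfg.det
    n_sp = len(cfg.E)
    duration_ms = cfg.duration_s * 1e3
    dt = cfg.dt_us * 1e-3  # ms

    z0 = 1.0 / det.s  # in units of w0
    D = 1.0 / (4.0 * det.t_diff)  # w0^2 / ms
    sig_step = np.sqrt(2.0 * D * dt)
    half = np.array([cfg.box_xy / 2, cfg.box_xy / 2, cfg.box_z / 2 * z0])

    # species-dependent emission: green ~ (1-E), red ~ gamma E + alpha (1-E)
    gE = 1.0 - cfg.E
    rE = det.gamma * cfg.E + det.alpha * (1.0 - cfg.E)
    tot_bright = gE + rE
    p_red = rE / tot_bright
    tau_D = cfg.tau_D0 * (1.0 - cfg.E)  # donor lifetime per species, ns

    # assign molecules: dynamic carries a CTMC, static a fixed state.
    # Stratified (largest-remainder) assignment keeps the realized
    # composition at the nominal fractions; a Bernoulli draw over a few
    # tens of molecules would give each run a visibly different mixture.
    n_mol = cfg.n_molecules
    n_dyn = int(np.round(cfg.p_d * n_mol))
    is_dyn = np.zeros(n_mol, dtype=bool)
    is_dyn[rng.permutation(n_mol)[:n_dyn]] = True
    # apportion static states among the static molecules only
    stat_states = np.repeat(
        np.arange(n_sp), _largest_remainder(cfg.x_static, n_mol - n_dyn)
    )
    rng.shuffle(stat_states)
    states_static = np.zeros(n_mol, dtype=int)
    states_static[~is_dyn] = stat_states
    traj = [None] * n_mol
    if cfg.mixture is not None and is_dyn.any():
        xd_net = equilibrium_fractions(cfg.mixture.net)
        dyn_idx = np.asarray(cfg.mixture.dynamic_states)
        for i in np.flatnonzero(is_dyn):
            jt, js = _gillespie_trajectory(
                rng, cfg.mixture.net.K, xd_net, duration_ms
            )
            traj[i] = (jt, dyn_idx[js])  # map network states -> species ids

    pos = rng.uniform(-half, half, size=(n_mol, 3))
    q_tot = det.Q0 * dt  # mean photons per step at the focus for brightness 1

    n_steps = int(np.floor(duration_ms / dt))
    chunk = max(1, int(5_000_000 / max(n_mol, 1)))
    ph_t, ph_mol = [], []
    step0 = 0
    while step0 < n_steps:
        nc = min(chunk, n_steps - step0)
        steps = rng.normal(0.0, sig_step, size=(nc, n_mol, 3))
        path = pos[None, :, :] + np.cumsum(steps, axis=0)
        # periodic wrap into the box
        path = (path + half) % (2.0 * half) - half
        pos = path[-1]
        W = np.exp(
            -2.0 * (path[:, :, 0] ** 2 + path[:, :, 1] ** 2)
            - 2.0 * (path[:, :, 2] / z0) ** 2
        )
        lam = q_tot * W  # brightness factor applied per photon below
        counts = rng.poisson(lam)
        sidx, midx = np.nonzero(counts)
        if len(sidx):
            reps = counts[sidx, midx]
            sidx = np.repeat(sidx, reps)
            midx = np.repeat(midx, reps)
            t_ph = (step0 + sidx + rng.random(len(sidx))) * dt
            ph_t.append(t_ph)
            ph_mol.append(midx)
        step0 += nc
    if ph_t:
        t_all = np.concatenate(ph_t)
        m_all = np.concatenate(ph_mol)
    else:
        t_all = np.empty(0)
        m_all = np.empty(0, dtype=int)

    # species of each photon's molecule at emission time
    sp = np.empty(len(t_all), dtype=np.int64)
    for i in range(n_mol):
        sel = m_all == i
        if not sel.any():
            continue
        if traj[i] is None:
            sp[sel] = states_static[i]
        else:
            jt, js = traj[i]
            k = np.searchsorted(jt, t_all[sel], side="right") - 1
            sp[sel] = js[k]

    # brightness thinning: keep each photon with prob tot_bright(species)/max
    bmax = tot_bright.max()
    keep = rng.random(len(t_all)) < tot_bright[sp] / bmax
    t_all, sp = t_all[keep], sp[keep]

    red = rng.random(len(t_all)) < p_red[sp]
    micro = np.where(
        red,
        rng.exponential(cfg.tau_A, size=len(t_all)),
        rng.exponential(np.clip(tau_D[sp], 1e-6, None)),
    )
    micro = np.mod(micro, cfg.micro_range_ns)  # TCSPC wrap-around

    order = np.argsort(t_all, kind="stable")
    return PhotonStream(
        macro_ms=t_all[order],
        channel=red[order].astype(np.uint8),
        micro_ns=micro[order].astype(np.float32),
        duration_ms=duration_ms,
        meta={"config": cfg, "mean_rate_khz": len(t_all) / duration_ms
              if duration_ms else 0.0,
              # mean occupancy of the effective (pi^3/2 w0^2 z0) volume and
              # the constant baseline a closed box (fixed N) adds to G
              "N_eff": n_mol * np.pi**1.5 / (cfg.box_xy**2 * cfg.box_z),
              "closed_box_offset": -1.0 / n_mol},
    )


def detect_bursts(
    stream: PhotonStream,
    window_ms: float = 0.5,
    min_in_window: int = 5,
    min_photons: int = 60,
) -> BurstTable:
    """Sliding-time-window burst search on the summed channel signal.

    A photon is burst-like if at least ``min_in_window`` photons fall in a
    centered window of ``window_ms``; runs of burst-like photons with at
    least ``min_photons`` photons form bursts.
    """
    t = stream.macro_ms
    if len(t) == 0:
        import warnings

        warnings.warn("empty photon stream; no bursts found", stacklevel=2)
        return _empty_bursts()
    lo = np.searchsorted(t, t - window_ms / 2, side="left")
    hi = np.searchsorted(t, t + window_ms / 2, side="right")
    keep = (hi - lo) >= min_in_window
    # run-length encode the kept mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], keep.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]

    rows = []
    green = stream.channel == 0
    for a, b in zip(starts, stops):
        if b - a < min_photons:
            continue
        g = int(green[a:b].sum())
        r = int((b - a) - g)
        tauF = float(stream.micro_ns[a:b][green[a:b]].mean()) if g else np.nan
        rows.append((t[a], t[b - 1], g, r, r / (g + r), tauF))
    if not rows:
        import warnings

        warnings.warn("no bursts passed the selection criteria", stacklevel=2)
        return _empty_bursts()
    arr = np.asarray(rows, dtype=float)
    return BurstTable(
        start_ms=arr[:, 0],
        stop_ms=arr[:, 1],
        n_green=arr[:, 2].astype(int),
        n_red=arr[:, 3].astype(int),
        E=arr[:, 4],
        tau_F_ns=arr[:, 5],
        meta={"window_ms": window_ms, "min_in_window": min_in_window,
              "min_photons": min_photons},
    )


def _empty_bursts() -> BurstTable:
    z = np.empty(0)
    return BurstTable(start_ms=z, stop_ms=z, n_green=z.astype(int),
                      n_red=z.astype(int), E=z, tau_F_ns=z)


def histogram2d(
    bursts: BurstTable,
    tau_D0: float,
    axes: str = "lifetime",
    bins: int = 61,
):
    """2D burst histogram in one of the standard FRET representations.

    ``axes``: ``"lifetime"`` -> (<tau_DA>_F, E); ``"moment"`` ->
    (m1, m2) = (1-E, (1-E)(1-E_tau)); ``"variance"`` -> (E, Var(E)).
    Returns ``(H, x_edges, y_edges)`` (H indexed [x, y]).
    """
    if len(bursts) == 0:
        raise ValueError("empty burst table")
    E = bursts.E
    E_tau = 1.0 - bursts.tau_F_ns / tau_D0
    if axes == "lifetime":
        x, y = bursts.tau_F_ns, E
        rng_ = [[0.0, tau_D0 * 1.05], [-0.05, 1.05]]
    elif axes == "moment":
        x = 1.0 - E
        y = (1.0 - E) * (1.0 - E_tau)
        rng_ = [[0.0, 1.05], [0.0, 1.05]]
    elif axes == "variance":
        x = E
        y = (1.0 - E) * (E - E_tau)
        rng_ = [[-0.05, 1.05], [-0.05, 0.3]]
    else:
        raise ValueError(f"unknown axes {axes!r}")
    H, xe, ye = np.histogram2d(x, y, bins=bins, range=rng_)
    return H, xe, ye


def window_counts(
    stream: PhotonStream,
    T_ms: float,
    min_photons: int = 20,
    bursts: BurstTable | None = None,
):
    """Green/red photon counts in consecutive time windows of length T.

    With ``bursts`` given, windows are cut from within each burst
    (burst-wise mode); otherwise the full stream is sliced.  Windows with
    fewer than ``min_photons`` photons are dropped (no molecule present).
    Returns ``(F, n_red)`` integer arrays (F = total photons per window).
    """
    t = stream.macro_ms
    red = stream.channel.astype(np.int64)
    if bursts is None:
        idx = (t / T_ms).astype(np.int64)
        nwin = int(stream.duration_ms / T_ms) + 1
        F = np.bincount(idx, minlength=nwin)
        NR = np.bincount(idx, weights=red, minlength=nwin).astype(np.int64)
    else:
        Fs, NRs = [], []
        for a, b in zip(bursts.start_ms, bursts.stop_ms):
            i0, i1 = np.searchsorted(t, (a, b + 1e-9))
            k = ((t[i0:i1] - a) / T_ms).astype(np.int64)
            nw = int((b - a) / T_ms) + 1
            f = np.bincount(k, minlength=nw)
            nr = np.bincount(k, weights=red[i0:i1], minlength=nw).astype(np.int64)
            full = (np.arange(nw) + 1) * T_ms <= (b - a) + T_ms * 1e-6
            Fs.append(f[full])
            NRs.append(nr[full])
        F = np.concatenate(Fs) if Fs else np.empty(0, dtype=int)
        NR = np.concatenate(NRs) if NRs else np.empty(0, dtype=int)
    good = F >= min_photons
    return F[good], NR[good]


def timewindow_histograms(
    stream: PhotonStream,
    T_list,
    bin_edges=None,
    min_photons: int = 20,
    bursts: BurstTable | None = None,
):
    """FRET-efficiency histograms for a list of window lengths.

    Returns ``{T: (hist, bin_edges)}`` with ``hist`` normalized to unit sum.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 41)
    out = {}
    for T in T_list:
        F, NR = window_counts(stream, T, min_photons=min_photons, bursts=bursts)
        if len(F) == 0:
            out[T] = (np.zeros(len(bin_edges) - 1), bin_edges)
            continue
        Ew = NR / F
        h, _ = np.histogram(Ew, bins=bin_edges)
        s = h.sum()
        out[T] = (h / s if s else h.astype(float), bin_edges)
    return out
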