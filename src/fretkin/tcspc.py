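"""Donor fluorescence decay models and synthetic TCSPC histograms.

For a mixture of FRET species with total fractions x_i and efficiencies
E_i, the donor decay (after short-pulse excitation, fluorescence and
kinetics timescales decoupled) is the species-fraction-weighted sum

    f(t) = sum_i x_i exp(-t / (tau_D0 (1 - E_i))) ,

i.e. weighting by molecule fractions exactly as a species-population
average, not by emitted photons.  A photon-weighted variant is provided as
a comparison utility (`decay_model_photon_weighted`) because the two
weightings differ measurably for heterogeneous mixtures.

Micro times in ns.  Default histogram range 0-25 ns with 4096 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecayHistogram",
    "decay_model",
    "decay_model_photon_weighted",
    "poisson_decay",
    "subensemble_decay",
    "fit_decay",
    "mean_lifetime_intensity_weighted",
]

MICRO_RANGE_NS = 25.0
N_BINS = 4096


@dataclass
class DecayHistogram:
    """A TCSPC decay: uniform micro-time bins (ns) and counts per bin."""

    bin_edges: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        w = np.diff(self.bin_edges)
        if not np.allclose(w, w[0], rtol=1e-6):
            raise ValueError("bin width must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def t(self) -> np.ndarray:
        """Bin centers in ns."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def sigma(self) -> np.ndarray:
        """Poisson uncertainties ``sqrt(counts)`` (1 where counts == 0)."""
        return np.sqrt(np.clip(self.counts, 1.0, None))


def _lifetimes(E, tau_D0: float):
    E = np.asarray(E, dtype=float)
    if np.any(E >= 1.0):
        raise ValueError(
            "species with E = 1 has zero donor lifetime and must be excluded"
        )
    return tau_D0 * (1.0 - E)


def decay_model(x_total, E, tau_D0: float, t) -> np.ndarray:
    """Species-fraction-weighted donor decay ``sum_i x_i e^{-t/tau_i}``."""
    x = np.asarray(x_total, dtype=float)
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    if tau_D0 <= 0:
        raise ValueError("tau_D0 must be positive")
    tau = _lifetimes(E, tau_D0)
    t = np.asarray(t, dtype=float)
    return np.exp(-t[:, None] / tau[None, :]) @ x


def decay_model_photon_weighted(x_total, E, tau_D0: float, t) -> np.ndarray:
    """Photon(species-brightness)-weighted decay, for comparison.

    Each species contributes in proportion to its emitted donor photons,
    ``x_i tau_i``, rather than its molecule fraction.
    """
    x = np.asarray(x_total, dtype=float)
    tau = _lifetimes(E, tau_D0)
    w = x * tau
    w = w / w.sum()
    t = np.asarray(t, dtype=float)
    return np.exp(-t[:, None] / tau[None, :]) @ w


def mean_lifetime_intensity_weighted(x_total, E, tau_D0: float) -> float:
    """Intensity-weighted mean lifetime ``<tau>_F = sum x tau^2 / sum x tau``."""
    x = np.asarray(x_total, dtype=float)
    tau = _lifetimes(E, tau_D0)
    return float((x * tau**2).sum() / (x * tau).sum())


def poisson_decay(
    model_values, total_counts: float, seed=None, bin_edges=None
) -> DecayHistogram:
    """Poisson realization of a model decay scaled to ``total_counts``.

    ``model_values`` are relative intensities on the bin grid; the scaled
    expectation is ``total_counts * model / sum(model)``.
    """
    model_values = np.asarray(model_values, dtype=float)
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, MICRO_RANGE_NS, len(model_values) + 1)
    rng = np.random.default_rng(seed)
    s = model_values.sum()
    lam = total_counts * model_values / s if s > 0 else model_values
    counts = rng.poisson(lam).astype(float)
    return DecayHistogram(bin_edges=np.asarray(bin_edges), counts=counts)


def subensemble_decay(
    stream,
    bursts=None,
    mask=None,
    n_bins: int = N_BINS,
    micro_range: float = MICRO_RANGE_NS,
) -> DecayHistogram:
    """Histogram donor-channel micro times of selected bursts.

    ``stream`` is a :class:`fretkin.simulate.PhotonStream`.  With ``bursts``
    (a :class:`fretkin.simulate.BurstTable`) and a boolean ``mask`` over its
    rows, only photons inside the selected bursts enter; with neither, the
    full stream is used (ensemble decay).
    """
    macro = stream.macro_ms
    green = stream.channel == 0
    if bursts is not None:
        if mask is None:
            mask = np.ones(len(bursts.start_ms), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty burst selection")
        starts = bursts.start_ms[mask]
        stops = bursts.stop_ms[mask]
        idx = np.searchsorted(starts, macro, side="right") - 1
        inside = (idx >= 0) & (macro <= stops[np.clip(idx, 0, None)])
        sel = green & inside
    else:
        sel = green
    if not sel.any():
        raise ValueError("selection contains no donor photons")
    edges = np.linspace(0.0, micro_range, n_bins + 1)
    counts, _ = np.histogram(stream.micro_ns[sel], bins=edges)
    return DecayHistogram(bin_edges=edges, counts=counts.astype(float))


def fit_decay(
    hist: DecayHistogram,
    n_components: int,
    tau_D0: float,
    E_init=None,
    fix_E=None,
):
    """Fit an ``n_components`` species model to a decay histogram.

    Model: ``A * sum_i x_i exp(-t/ (tau_D0 (1-E_i)))`` with Poisson
    weights; the scale A is profiled analytically each iteration.  Returns
    an ``lmfit.MinimizerResult``-like object with ``params`` containing
    ``E1..En`` and ``x1..xn`` plus ``redchi``.
    """
    import lmfit

    t = hist.t
    y = hist.counts
    sig = hist.sigma()

    params = lmfit.Parameters()
    if E_init is None:
        E_init = np.linspace(0.15, 0.85, n_components)
    for i in range(n_components):
        vary = not (fix_E is not None and fix_E[i] is not None)
        val = E_init[i] if vary else fix_E[i]
        params.add(f"E{i + 1}", value=val, min=0.0, max=0.99, vary=vary)
    # fractions via unconstrained softmax-style logits for stability
    for i in range(n_components - 1):
        params.add(f"g{i + 1}", value=0.0, min=-10, max=10)

    def fractions(p):
        g = np.array([p[f"g{i + 1}"] for i in range(n_components - 1)] + [0.0])
        w = np.exp(g - g.max())
        return w / w.sum()

    def resid(p):
        E = np.array([p[f"E{i + 1}"] for i in range(n_components)])
        x = fractions(p)
        m = decay_model(x, E, tau_D0, t)
        scale = (y * m / sig**2).sum() / (m**2 / sig**2).sum()
        return (y - scale * m) / sig

    out = lmfit.minimize(resid, params, method="least_squares")
    E_hat = np.array([out.params[f"E{i + 1}"].value for i in range(n_components)])
    x_hat = fractions(out.params)
    order = np.argsort(E_hat)
    out.E = E_hat[order]
    out.x = x_hat[order]
    return out
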