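"""Filtered-FCS: species-selective correlation via micro-time filters.

Each fluorescence species has a characteristic pattern over the joint
(detection channel x TCSPC micro-time bin) histogram: the donor channel
carries its FRET-quenched donor decay, the red channel the acceptor decay,
with channel weights set by the efficiency.  Given the patterns p^(i)
(unit-sum over bins) and the measured/modelled total histogram W(t), the
filter matrix

    F = (P^T D P)^-1 P^T D,      D = diag(1 / W(t)),

is the minimum-variance linear estimator of the per-species photon
contributions under Poisson bin noise, and satisfies F P = I exactly
(unbiasedness): applying filter i to photons of pure species j returns
delta_ij times its photon count.  Correlating filter-weighted photon
streams then yields species auto- (sACF) and cross-correlation (sCCF)
functions whose rise/decay pattern reveals the kinetic connectivity:
directly exchanging species show a fast-rising sCCF, species connected
only through an intermediate show a delayed rise, and species with no
exchange show no kinetic amplitude at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlate import correlate_photons
from .fcsfit import fit_correlations_global

__all__ = [
    "FilterSet",
    "model_patterns",
    "build_filters",
    "photon_weights",
    "species_correlations",
    "fit_species_correlations",
]


@dataclass
class FilterSet:
    """Per-species filter weights over the (channel x micro-bin) index."""

    filters: np.ndarray  # (n_species, 2 * n_bins)
    patterns: np.ndarray  # (n_species, 2 * n_bins), unit sum each
    labels: tuple
    n_bins: int
    micro_range_ns: float
    condition_number: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return self.filters.shape[0]


def model_patterns(
    E,
    tau_D0: float,
    tau_A: float = 1.0,
    gamma: float = 1.0,
    alpha: float = 0.0,
    n_bins: int = 64,
    micro_range_ns: float = 25.0,
):
    """Noise-free decay patterns of each species over (channel, micro bin).

    Green-channel bins carry the donor decay with lifetime
    tau_D0 (1 - E_i), red bins the acceptor decay; channel weights are the
    green/red photon fractions of the species.  Rows sum to one.
    """
    E = np.asarray(E, dtype=float)
    edges = np.linspace(0.0, micro_range_ns, n_bins + 1)

    def bin_exp(tau):
        # exact bin integrals of a wrapped exponential decay
        w = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        return w / w.sum()

    pats = np.zeros((len(E), 2 * n_bins))
    for i, Ei in enumerate(E):
        gw = 1.0 - Ei
        rw = gamma * Ei + alpha * (1.0 - Ei)
        tot = gw + rw
        tau_D = tau_D0 * max(1.0 - Ei, 1e-6)
        pats[i, :n_bins] = (gw / tot) * bin_exp(tau_D)
        pats[i, n_bins:] = (rw / tot) * bin_exp(tau_A)
    return pats, edges


def build_filters(
    patterns: np.ndarray,
    mixture_weights,
    labels=None,
    n_bins: int | None = None,
    micro_range_ns: float = 25.0,
    cond_warn: float = 1e6,
) -> FilterSet:
    """Weighted least-squares filters from species patterns.

    ``mixture_weights`` are the photon fractions of the species in the
    measured mixture (used to form the expected total histogram that sets
    the Poisson weights).  Raises on (near-)degenerate patterns, naming
    the collinear pair; warns and reports the condition number when a pair
    is nearly degenerate.
    """
    P = np.asarray(patterns, dtype=float).T  # (n_idx, n_species)
    w = np.asarray(mixture_weights, dtype=float)
    n_idx, n_sp = P.shape
    if n_bins is None:
        n_bins = n_idx // 2
    if labels is None:
        labels = tuple(f"S{i + 1}" for i in range(n_sp))
    W_tot = P @ (w / w.sum())
    good = W_tot > 1e-12
    D = np.zeros(n_idx)
    D[good] = 1.0 / W_tot[good]
    M = (P.T * D) @ P  # (n_sp, n_sp) normal matrix
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > 1e12:
        # name the most collinear pair via pattern correlations
        C = np.corrcoef(np.asarray(patterns, dtype=float))
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        raise ValueError(
            f"degenerate species patterns: {labels[i]} and {labels[j]} are "
            "collinear (identical lifetimes?)"
        )
    if cond > cond_warn:
        import warnings

        warnings.warn(
            f"nearly degenerate species patterns (condition number {cond:.3g})",
            stacklevel=2,
        )
    F = np.linalg.solve(M, P.T * D)  # (n_sp, n_idx)
    return FilterSet(
        filters=F,
        patterns=np.asarray(patterns, dtype=float),
        labels=tuple(labels),
        n_bins=n_bins,
        micro_range_ns=micro_range_ns,
        condition_number=cond,
    )


def photon_weights(stream, filters: FilterSet) -> np.ndarray:
    """Per-photon filter weights, shape (n_species, n_photons)."""
    nb = filters.n_bins
    bidx = np.clip(
        (stream.micro_ns / filters.micro_range_ns * nb).astype(np.int64),
        0,
        nb - 1,
    )
    idx = stream.channel.astype(np.int64) * nb + bidx
    return filters.filters[:, idx]


def species_correlations(
    stream,
    filters: FilterSet,
    bin_ms: float = 0.005,
    n_blocks: int = 16,
    pairs=None,
):
    """Species auto-/cross-correlations of a photon stream.

    Returns ``{(label_a, label_b): CorrelationCurve}`` for every ordered
    pair requested (default: all pairs, n_species^2 curves).
    """
    w = photon_weights(stream, filters)
    t = stream.macro_ms
    labels = filters.labels
    if pairs is None:
        pairs = [(a, b) for a in labels for b in labels]
    out = {}
    for a, b in pairs:
        ia, ib = labels.index(a), labels.index(b)
        out[(a, b)] = correlate_photons(
            t, t, stream.duration_ms, bin_ms=bin_ms,
            weights_a=w[ia], weights_b=w[ib],
            n_blocks=n_blocks, pair=f"{a}-{b}",
        )
    return out


def half_rise_time(a0: float, amps, t_rs) -> float:
    """Half-rise (or half-decay) time of a fitted kinetic factor.

    The kinetic part ``kin(t) = a0 + sum_l a_l e^{-t/t_l}`` runs from
    ``kin(0)`` to the plateau ``a0``; returns the time at which it first
    crosses the midpoint.  Species pairs exchanging only through an
    intermediate state show a delayed (sigmoidal) rise and hence a larger
    half-rise time than directly connected pairs.
    """
    amps = np.asarray(amps, dtype=float)
    t_rs = np.asarray(t_rs, dtype=float)
    t = np.geomspace(max(t_rs.min() * 1e-3, 1e-6), t_rs.max() * 20.0, 4000)
    kin = a0 + (amps[None, :] * np.exp(-t[:, None] / t_rs[None, :])).sum(axis=1)
    k0 = a0 + amps.sum()
    mid = 0.5 * (k0 + a0)
    crossed = (kin - mid) * np.sign(a0 - k0) >= 0
    if not crossed.any():
        return float("nan")
    return float(t[int(np.argmax(crossed))])


def fit_species_correlations(
    curves,
    n_relaxations: int = 1,
    s: float = 0.25,
    t_diff_init: float = 2.0,
    lag_max: float = np.inf,
    **kw,
):
    """Global kinetic fit of species correlation curves.

    Shares the relaxation-time set and the diffusion time across all
    curves, amplitudes free per curve (the standard fFCS analysis).
    ``curves`` may be a dict (values are used) or a list.  Warns when the
    model is over-parameterized (n_relaxations >= n_species).
    """
    if isinstance(curves, dict):
        labels = {c.pair for c in curves.values()}
        n_sp = len({s_ for p in labels for s_ in p.split("-")})
        curve_list = list(curves.values())
    else:
        curve_list = list(curves)
        n_sp = None
    if n_sp is not None and n_relaxations >= n_sp:
        import warnings

        warnings.warn(
            f"{n_relaxations} relaxation times for {n_sp} species "
            "over-parameterizes the kinetic model (expect n_species - 1)",
            stacklevel=2,
        )
    return fit_correlations_global(
        curve_list,
        n_relaxations=n_relaxations,
        s=s,
        t_diff_init=t_diff_init,
        lag_max=lag_max,
        **kw,
    )
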