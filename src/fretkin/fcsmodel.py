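"""Analytic color-FCS model functions for multi-state kinetic networks.

The normalized correlation between detection channels a and b of a solution
of freely diffusing molecules that additionally switch conformational
states factorizes (diffusion and kinetics being independent) into

    G_ab(t_c) = (1/N) G_diff(t_c) G_k,ab(t_c) + 1 ,

with the 3D-Gaussian diffusion factor G_diff and the kinetic factor

    G_k,ab(t_c) = S_a^T G(t_c) S_b / (S_a_bar S_b_bar) ,
    G(t_c)      = p_d exp(K t_c) X_d + (1 - p_d) X_s ,

where S_a, S_b are per-species signal vectors, X_d and X_s diagonal
matrices of the dynamic and static state fractions, and p_d the fraction of
molecules participating in exchange.  Expanding exp(K t_c) over the
spectral projectors of K turns G_k into a constant plus n-1 exponentials
whose decay rates are the network's relaxation rates; the amplitudes are
pairwise species contrasts weighted by fraction (co)fluctuations.

Channel signal vectors for a donor/acceptor ("green"/"red") experiment:

    q_G = Q0 (1 - E),     q_R = Q0 (gamma E + alpha (1 - E)),

with crosstalk alpha and detection/quantum-yield correction gamma; the
brightness scale Q0 cancels in the normalized correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticNetwork, eigen_decompose, equilibrium_fractions

__all__ = [
    "MixtureModel",
    "DetectionModel",
    "CorrelationCurve",
    "diffusion_term",
    "kinetic_correlation",
    "kinetic_amplitudes",
    "contrast_factors",
    "color_fcs_curve",
    "amplitudes_from_indicators",
    "multitau_grid",
]


@dataclass(frozen=True)
class MixtureModel:
    """Coexisting dynamic and static molecules over a common species set.

    ``net`` is the kinetic network of the dynamic molecules.  If the
    species set is larger than the network (static-only species), pass
    ``dynamic_states``: indices of the species the network states map onto.
    ``x_s`` are the state fractions of the static molecules (length =
    number of species); ``p_d`` the fraction of dynamic molecules.
    """

    net: KineticNetwork
    p_d: float
    x_s: np.ndarray
    dynamic_states: tuple | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_d <= 1.0:
            raise ValueError("p_d must lie in [0, 1]")
        x_s = np.asarray(self.x_s, dtype=float)
        if abs(x_s.sum() - 1.0) > 1e-8 or np.any(x_s < -1e-12):
            raise ValueError("x_s must be nonnegative and sum to 1")
        object.__setattr__(self, "x_s", x_s)
        dyn = self.dynamic_states
        if dyn is None:
            dyn = tuple(range(self.net.n_states))
        else:
            dyn = tuple(int(i) for i in dyn)
        if len(dyn) != self.net.n_states:
            raise ValueError("dynamic_states must list one species per network state")
        if any(not 0 <= i < self.n_species for i in dyn):
            raise ValueError("dynamic_states out of range")
        object.__setattr__(self, "dynamic_states", dyn)

    @property
    def n_species(self) -> int:
        return len(self.x_s)

    @property
    def x_d(self) -> np.ndarray:
        """Dynamic-state fractions embedded on the full species set."""
        xd_net = equilibrium_fractions(self.net)
        x = np.zeros(self.n_species)
        x[list(self.dynamic_states)] = xd_net
        return x

    @property
    def x_total(self) -> np.ndarray:
        """Total species fractions ``x = p_d x_d + (1 - p_d) x_s``."""
        return self.p_d * self.x_d + (1.0 - self.p_d) * self.x_s


@dataclass(frozen=True)
class DetectionModel:
    """Detection geometry and photophysical corrections.

    ``t_diff`` in ms, aspect ``s = w0/z0``, mean occupancy ``N_mol`` of the
    effective volume, donor brightness ``Q0`` in kHz (cancels in G).
    """

    t_diff: float = 5.0
    s: float = 0.25
    N_mol: float = 1.0
    Q0: float = 150.0
    gamma: float = 1.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.t_diff <= 0 or not 0 < self.s <= 1:
            raise ValueError("need t_diff > 0 and s in (0, 1]")
        if self.gamma <= 0 or not 0.0 <= self.alpha < 1.0:
            raise ValueError("need gamma > 0 and alpha in [0, 1)")

    def signal_vectors(self, E) -> tuple[np.ndarray, np.ndarray]:
        """Per-species (green, red) signal vectors from efficiencies."""
        E = np.asarray(E, dtype=float)
        qG = self.Q0 * (1.0 - E)
        qR = self.Q0 * (self.gamma * E + self.alpha * (1.0 - E))
        return qG, qR


@dataclass
class CorrelationCurve:
    """A correlation curve on a (quasi-logarithmic) lag grid.

    ``lag`` in ms (strictly increasing), ``G`` the normalized correlation
    and ``sigma`` optional per-point uncertainties.  ``pair`` labels the
    correlated channels or species, e.g. ``"GR"`` or ``"LF-HF"``.
    """

    lag: np.ndarray
    G: np.ndarray
    sigma: np.ndarray | None = None
    pair: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lag = np.asarray(self.lag, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


def multitau_grid(t_min: float = 1e-4, t_max: float = 100.0, per_cascade: int = 16):
    """Quasi-logarithmic lag grid in ms, multi-tau style (doubling cascades)."""
    lags = [t_min * (i + 1) for i in range(per_cascade)]
    dt = t_min
    while lags[-1] < t_max:
        dt *= 2.0
        start = lags[-1]
        for i in range(per_cascade // 2):
            nxt = start + dt * (i + 1)
            if nxt > t_max:
                break
            lags.append(nxt)
        else:
            continue
        break
    return np.asarray(lags)


def diffusion_term(t_c, t_diff: float, s: float = 0.25):
    """3D-Gaussian diffusion factor ``(1+t/t_d)^-1 (1+s^2 t/t_d)^-1/2``."""
    t_c = np.asarray(t_c, dtype=float)
    if np.any(t_c < 0):
        raise ValueError("lag times must be nonnegative")
    r = t_c / t_diff
    return 1.0 / (1.0 + r) / np.sqrt(1.0 + s**2 * r)


def _embedded_propagator_terms(model: MixtureModel):
    """Eigenvalues and embedded ``p_d Gamma^l X_d`` matrices on species space."""
    es = eigen_decompose(model.net)
    xd_net = equilibrium_fractions(model.net)
    idx = list(model.dynamic_states)
    n_sp = model.n_species
    terms = []
    for lam, gam in zip(es.eigenvalues, es.projectors):
        M = np.zeros((n_sp, n_sp))
        M[np.ix_(idx, idx)] = model.p_d * gam * xd_net[None, :]
        terms.append((float(lam), M))
    return terms


def kinetic_correlation(model: MixtureModel, S_a, S_b, t_c):
    """Kinetic factor ``G_k,ab`` on a lag grid (direct matrix route).

    Computes ``S_a^T [p_d e^{K t} X_d + (1-p_d) X_s] S_b / (S_a_bar S_b_bar)``
    through the spectral expansion of the propagator.
    """
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    t_c = np.asarray(t_c, dtype=float)
    x = model.x_total
    Sa_bar = S_a @ x
    Sb_bar = S_b @ x
    if Sa_bar == 0 or Sb_bar == 0:
        raise ValueError("mean signal is zero; kinetic correlation undefined")
    static = (1.0 - model.p_d) * np.sum(model.x_s * S_a * S_b)
    G = np.full(t_c.shape, static)
    for lam, M in _embedded_propagator_terms(model):
        G = G + (S_a @ M @ S_b) * np.exp(lam * t_c)
    return G / (Sa_bar * Sb_bar)


def kinetic_amplitudes(model: MixtureModel, S_a, S_b, prune: float = 1e-14):
    """Amplitude expansion ``G_k = 1 + A0 + sum_l A_l exp(lambda_l t)``.

    Returns ``(A0, [(lambda_l, A_l), ...])`` with terms of negligible
    amplitude pruned.  ``1 + A0`` is the long-time plateau of the kinetic
    factor (the static residual); the exponential amplitudes are
    ``A_l = p_d S_a^T Gamma^l X_d S_b / (S_a_bar S_b_bar)`` for l >= 1.
    """
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    x = model.x_total
    denom = (S_a @ x) * (S_b @ x)
    if denom == 0:
        raise ValueError("mean signal is zero")
    terms = _embedded_propagator_terms(model)
    static = (1.0 - model.p_d) * np.sum(model.x_s * S_a * S_b)
    # stationary (lambda = 0) mode + static part forms the plateau 1 + A0
    plateau = (static + S_a @ terms[0][1] @ S_b) / denom
    A0 = plateau - 1.0
    exps = []
    for lam, M in terms[1:]:
        A = (S_a @ M @ S_b) / denom
        if abs(A) >= prune:
            exps.append((lam, float(A)))
    return float(A0), exps


def contrast_factors(S_a, S_b, x_total):
    """Pairwise species contrast matrix ``d_ab^{ij}``.

        d_ab^{ij} = (S_a^i - S_a^j)(S_b^i - S_b^j) / (S_a_bar S_b_bar)
    """
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    x = np.asarray(x_total, dtype=float)
    Sa_bar = S_a @ x
    Sb_bar = S_b @ x
    da = S_a[:, None] - S_a[None, :]
    db = S_b[:, None] - S_b[None, :]
    return da * db / (Sa_bar * Sb_bar)


def color_fcs_curve(
    model: MixtureModel,
    det: DetectionModel,
    E,
    pair: str = "GG",
    t_c=None,
) -> CorrelationCurve:
    """Full color-FCS curve ``G = (1/N) G_diff G_k + 1`` for a channel pair.

    ``E`` lists the species FRET efficiencies; ``pair`` is one of
    ``GG, RR, GR, RG``.
    """
    if t_c is None:
        t_c = multitau_grid()
    t_c = np.asarray(t_c, dtype=float)
    qG, qR = det.signal_vectors(E)
    chans = {"G": qG, "R": qR}
    try:
        S_a, S_b = chans[pair[0]], chans[pair[1]]
    except (KeyError, IndexError):
        raise ValueError(f"unknown channel pair {pair!r}") from None
    Gk = kinetic_correlation(model, S_a, S_b, t_c)
    G = diffusion_term(t_c, det.t_diff, det.s) * Gk / det.N_mol + 1.0
    return CorrelationCurve(lag=t_c, G=G, pair=pair)


def amplitudes_from_indicators(ind) -> tuple[float, float, float]:
    """Molecule-wise kinetic correlation amplitudes from FRET indicators.

        G_k,GG(0) = Var(E)/(1-E)^2,  G_k,RR(0) = Var(E)/E^2,
        G_k,GR(0) = -Var(E)/((1-E) E),

    with ``Var(E) = (1-E)(E - E_tau)`` estimated per burst.  The identity
    ``G_GR(0)^2 = G_GG(0) G_RR(0)`` holds exactly.
    """
    from .fretlines import variance_from_indicators

    E = ind.E
    if E <= 0.0 or E >= 1.0:
        raise ZeroDivisionError("amplitudes undefined at E = 0 or 1")
    var = variance_from_indicators(ind, warn_unphysical=False)
    return (
        var / (1.0 - E) ** 2,
        var / E**2,
        -var / ((1.0 - E) * E),
    )
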