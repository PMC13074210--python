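"""Joint TCSPC + FCS analysis of static/dynamic mixtures.

The global objective sums the weighted squared residuals of one donor
decay histogram (Poisson sigma) and the four color correlation curves
(bootstrap sigma):  chi2_global = chi2_TCSPC + chi2_FCS.

The model for a three-species mixture with one exchanging pair has nine
microscopic parameters: the species efficiencies E^(i), the exchange
rates (k12, k21) of the dynamic pair, two independent static fractions,
the dynamic-molecule fraction p_d, and the diffusion parameters
(t_diff, N).  TCSPC constrains E^(i) and the total fractions x; FCS adds
the relaxation time t_R = 1/(k12+k21) and the kinetic amplitude, which
depends on the microscopic parameters only through p_d x_d1 x_d2.  The
experiment therefore determines seven quantities: the model is
inherently underdetermined, with the one-parameter ambiguity manifold

    p_d k12 k21 = p_d k12 (1/t_R - k12) = const        (at fixed t_R)

and a discrete ambiguity among the assignments of the dynamic pair
(which two of the three species exchange).  Both are exposed here: MCMC
sampling traces the continuous manifold, and `enumerate_schemes` +
per-scheme fits expose the discrete branches; external knowledge (p_d
from PDA, or x_d from the FRET-line position of the dynamic population)
resolves them via `resolve_with_pd` / `resolve_with_xd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .fcsmodel import (
    CorrelationCurve,
    DetectionModel,
    MixtureModel,
    diffusion_term,
    kinetic_correlation,
)
from .kinetics import build_rate_matrix
from .tcspc import DecayHistogram, decay_model

__all__ = [
    "GlobalData",
    "GlobalModel",
    "FitResult",
    "chi2_global",
    "fit_global",
    "mcmc_sample",
    "enumerate_schemes",
    "resolve_with_pd",
    "resolve_with_xd",
]

PARAM_NAMES_3 = (
    "E1", "E2", "E3", "k12", "k21", "xs1", "xs2", "p_d", "t_diff", "N",
)


@dataclass
class GlobalData:
    """One decay histogram plus color correlation curves (GG, GR, RG, RR)."""

    decay: DecayHistogram
    curves: dict  # pair label -> CorrelationCurve
    tau_D0: float = 4.0
    s: float = 0.25
    fcs_offset: float | None = None  # known additive baseline (else fitted)
    sigma_floor_frac: float = 0.1  # floor on FCS sigma vs per-curve median
    lag_max_ms: float = np.inf  # crop lags (finite-box wrap tails, noise)

    def __post_init__(self):
        if np.isfinite(self.lag_max_ms):
            for p, c in list(self.curves.items()):
                keep = c.lag <= self.lag_max_ms
                self.curves[p] = CorrelationCurve(
                    lag=c.lag[keep], G=c.G[keep],
                    sigma=None if c.sigma is None else c.sigma[keep],
                    pair=c.pair, meta=c.meta,
                )
        for p, c in self.curves.items():
            if c.sigma is None or np.any(c.sigma <= 0):
                raise ValueError(f"curve {p} lacks positive sigma weights")
            if self.sigma_floor_frac > 0:
                floor = self.sigma_floor_frac * np.median(c.sigma)
                c.sigma = np.maximum(c.sigma, floor)


@dataclass
class GlobalModel:
    """Parameter vector + kinetic scheme for the global fit.

    ``scheme`` is the ordered index pair (i, j) of the exchanging species:
    k12 is the rate j -> i (so x_d(i) = k12/(k12+k21)).  ``values`` maps
    parameter names to values; ``E{n}`` efficiencies sorted ascending by
    species index, ``xs1``/``xs2`` the first two static fractions.
    """

    n_species: int
    scheme: tuple
    values: dict
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    offset_pairs: tuple = ()  # curve pairs with a free additive baseline
    #: curve pairs with a bounded multiplicative amplitude calibration
    #: (absorbs the few-percent amplitude uncertainty of finite
    #: measurements so it cannot bias the relaxation time)
    scale_pairs: tuple = ()

    DEFAULT_BOUNDS = {
        "E": (0.01, 0.99), "k": (0.01, 100.0), "xs": (0.0, 1.0),
        "p_d": (0.0, 1.0), "t_diff": (0.1, 100.0), "N": (0.01, 100.0),
        "c": (-0.2, 0.2), "s": (0.8, 1.25),
    }

    def param_names(self):
        names = [f"E{i + 1}" for i in range(self.n_species)]
        names += ["k12", "k21"]
        names += [f"xs{i + 1}" for i in range(self.n_species - 1)]
        names += ["p_d", "t_diff", "N"]
        names += [f"c_{p}" for p in self.offset_pairs]
        names += [f"s_{p}" for p in self.scale_pairs]
        return [n for n in names if n not in self.fixed]

    def bound_of(self, name):
        if name in self.bounds:
            return self.bounds[name]
        if name.startswith("c_"):
            return self.DEFAULT_BOUNDS["c"]
        if name.startswith("s_"):
            return self.DEFAULT_BOUNDS["s"]
        key = "".join(ch for ch in name if not ch.isdigit())
        return self.DEFAULT_BOUNDS.get(key, (-np.inf, np.inf))

    def full_values(self, theta=None):
        vals = dict(self.values)
        for p in self.offset_pairs:
            vals.setdefault(f"c_{p}", 0.0)
        for p in self.scale_pairs:
            vals.setdefault(f"s_{p}", 1.0)
        vals.update(self.fixed)
        if theta is not None:
            for n, v in zip(self.param_names(), theta):
                vals[n] = float(v)
        return vals

    def mixture(self, vals) -> tuple[MixtureModel, np.ndarray]:
        n = self.n_species
        E = np.array([vals[f"E{i + 1}"] for i in range(n)])
        xs = np.empty(n)
        xs[:-1] = [vals[f"xs{i + 1}"] for i in range(n - 1)]
        xs[-1] = 1.0 - xs[:-1].sum()
        i, j = self.scheme
        net = build_rate_matrix(2, {(1, 0): vals["k12"], (0, 1): vals["k21"]})
        mix = MixtureModel(
            net=net, p_d=vals["p_d"], x_s=xs, dynamic_states=(i, j)
        )
        return mix, E


def _model_curves(model: GlobalModel, vals, data: GlobalData):
    mix, E = model.mixture(vals)
    det = DetectionModel(t_diff=vals["t_diff"], s=data.s, N_mol=vals["N"])
    qG, qR = det.signal_vectors(E)
    chans = {"G": qG, "R": qR}
    out = {}
    for pair, curve in data.curves.items():
        S_a, S_b = chans[pair[0]], chans[pair[1]]
        Gk = kinetic_correlation(mix, S_a, S_b, curve.lag)
        Gd = diffusion_term(curve.lag, vals["t_diff"], data.s)
        c = vals.get(f"c_{pair}", data.fcs_offset or 0.0)
        sc = vals.get(f"s_{pair}", 1.0)
        out[pair] = 1.0 + sc * Gd * Gk / vals["N"] + c
    return out, mix, E


def _residuals(model: GlobalModel, vals, data: GlobalData):
    try:
        mix, E = model.mixture(vals)
    except ValueError:
        return None
    x_total = mix.x_total
    if np.any(x_total < -1e-9):
        return None
    t = data.decay.t
    m = decay_model(x_total, E, data.tau_D0, t)
    y = data.decay.counts
    sig = data.decay.sigma()
    scale = (y * m / sig**2).sum() / (m**2 / sig**2).sum()
    res = [(y - scale * m) / sig]
    curves, _, _ = _model_curves(model, vals, data)
    for pair, curve in data.curves.items():
        res.append((curve.G - curves[pair]) / curve.sigma)
    return np.concatenate(res)


def chi2_global(model: GlobalModel, data: GlobalData, theta=None) -> float:
    """Global chi-square of the decay + correlation curves."""
    vals = model.full_values(theta)
    xs_last = 1.0 - sum(vals[f"xs{i + 1}"] for i in range(model.n_species - 1))
    if xs_last < -1e-9:
        return np.inf
    r = _residuals(model, vals, data)
    return float("inf") if r is None else float(r @ r)


@dataclass
class FitResult:
    model: GlobalModel
    values: dict
    chi2: float
    chi2_r: float
    n_data: int
    success: bool
    scheme: tuple
    physical: bool

    @property
    def relaxation_time_ms(self) -> float:
        return 1.0 / (self.values["k12"] + self.values["k21"])


def fit_global(
    data: GlobalData,
    model: GlobalModel,
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Bounded least-squares fit with Latin-hypercube multi-start.

    The residual vector (not the scalar chi2) is minimized so the solver
    sees a proper Jacobian.  Returns the best converged solution; if no
    start converges the best-so-far is returned with ``success=False``.
    """
    from scipy.optimize import least_squares
    from scipy.stats import qmc

    names = model.param_names()
    lo = np.array([model.bound_of(n)[0] for n in names])
    hi = np.array([model.bound_of(n)[1] for n in names])

    def resid(theta):
        vals = model.full_values(theta)
        xs_sum = sum(vals[f"xs{i + 1}"] for i in range(model.n_species - 1))
        r = _residuals(model, vals, data) if xs_sum <= 1.0 else None
        if r is None:
            return np.full(_ndata(data), 1e6)
        return r

    theta0 = np.array([model.full_values()[n] for n in names])
    starts = [np.clip(theta0, lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        pts = lo + sampler.random(n_starts - 1) * (hi - lo)
        starts += list(pts)
    best = None
    for th0 in starts:
        try:
            res = least_squares(resid, th0, bounds=(lo, hi), xtol=1e-10,
                                ftol=1e-10, max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    vals = model.full_values(best.x)
    chi2 = 2.0 * best.cost
    nd = _ndata(data)
    xs = [vals[f"xs{i + 1}"] for i in range(model.n_species - 1)]
    xs.append(1.0 - sum(xs))
    physical = all(-1e-6 <= v <= 1 + 1e-6 for v in xs) and 0 <= vals["p_d"] <= 1
    return FitResult(
        model=model, values=vals, chi2=chi2,
        chi2_r=chi2 / max(nd - len(names), 1), n_data=nd,
        success=bool(best.status > 0), scheme=model.scheme, physical=physical,
    )


def _ndata(data: GlobalData) -> int:
    return len(data.decay.counts) + sum(len(c.G) for c in data.curves.values())


def mcmc_sample(
    data: GlobalData,
    model: GlobalModel,
    n_walkers: int = 64,
    n_steps: int = 5000,
    burn_frac: float = 0.2,
    seed: int = 0,
    init_scale: float = 1e-3,
    p0=None,
):
    """Affine-invariant ensemble sampling of exp(-chi2/2) within bounds.

    Walkers start in a tight ball around the current model values (run
    `fit_global` first) unless an explicit ``p0`` array of shape
    ``(n_walkers, n_params)`` is given — e.g. spread along a known
    degeneracy manifold to probe its flatness.  Returns
    ``(flat_chain, flat_chi2, names)`` after burn-in removal.
    """
    import emcee

    names = model.param_names()
    lo = np.array([model.bound_of(n)[0] for n in names])
    hi = np.array([model.bound_of(n)[1] for n in names])

    def lnprob(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        vals = model.full_values(theta)
        xs_sum = sum(vals[f"xs{i + 1}"] for i in range(model.n_species - 1))
        if xs_sum > 1.0:
            return -np.inf
        r = _residuals(model, vals, data)
        if r is None:
            return -np.inf
        return -0.5 * float(r @ r)

    rng = np.random.default_rng(seed)
    if p0 is None:
        theta0 = np.array([model.full_values()[n] for n in names])
        p0 = theta0 + init_scale * (hi - lo) * rng.standard_normal(
            (n_walkers, len(names))
        )
    p0 = np.clip(np.asarray(p0, dtype=float), lo + 1e-9, hi - 1e-9)
    sampler = emcee.EnsembleSampler(n_walkers, len(names), lnprob)
    state = sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    if sampler.acceptance_fraction.mean() < 1e-3:
        raise RuntimeError("MCMC acceptance collapsed; adjust step scale")
    burn = int(burn_frac * n_steps)
    chain = sampler.get_chain(discard=burn, flat=True)
    chi2 = -2.0 * sampler.get_log_prob(discard=burn, flat=True)
    return chain, chi2, names


def enumerate_schemes(n_states: int, labels=None):
    """All assignments of one exchanging pair among ``n_states`` species."""
    if n_states < 2:
        raise ValueError("need at least two states")
    idx = list(combinations(range(n_states), 2))
    if labels is None:
        return idx
    return [((labels[i], labels[j]), (i, j)) for i, j in idx]


def resolve_with_pd(amp_product: float, t_R_ms: float, p_d: float):
    """Microscopic rates from the FCS observables and a known ``p_d``.

    ``amp_product`` is the experimentally determined p_d x_d1 x_d2.
    Solves x_d1 (1-x_d1) = amp_product / p_d; the two roots are the
    k12 <-> k21 assignment ambiguity.  Returns a list of
    ``(k12, k21, p_d)`` solutions (ms^-1).
    """
    if not 0 < p_d <= 1:
        raise ValueError("p_d must be in (0, 1]")
    q = amp_product / p_d
    disc = 1.0 - 4.0 * q
    if disc < -1e-9:
        raise ValueError(
            "no intersection: amplitude product exceeds p_d/4 "
            "(constraint inconsistent with the manifold)"
        )
    disc = max(disc, 0.0)
    roots = sorted({(1.0 + np.sqrt(disc)) / 2.0, (1.0 - np.sqrt(disc)) / 2.0})
    return [(x1 / t_R_ms, (1.0 - x1) / t_R_ms, p_d) for x1 in roots]


def resolve_with_xd(amp_product: float, t_R_ms: float, x_d1: float):
    """Microscopic rates and p_d from a known dynamic fraction x_d1.

    x_d1 is read off the FRET-line position of the dynamic population (or
    obtained by mode inversion); then k12 = x_d1/t_R, k21 = (1-x_d1)/t_R
    and p_d = amp_product / (x_d1 (1 - x_d1)).
    """
    if not 0 < x_d1 < 1:
        raise ValueError("x_d1 must be in (0, 1)")
    p_d = amp_product / (x_d1 * (1.0 - x_d1))
    if p_d > 1 + 1e-6:
        raise ValueError("implied p_d exceeds 1: constraint inconsistent")
    return x_d1 / t_R_ms, (1.0 - x_d1) / t_R_ms, min(p_d, 1.0)
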