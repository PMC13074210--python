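"""Dynamic photon distribution analysis (PDA).

Models the shape of FRET-efficiency histograms obtained for fixed time
windows of length T.  Conditional on a window catching F photons from a
molecule whose efficiency over the window is E, the red count is binomial,
N_R ~ Bin(F, eps(E)) with eps(E) = (gamma E + alpha(1-E)) / (gamma E +
(1+alpha)(1-E)) (= E for ideal detection).  The distribution of E is the
mixture of

* static species: point masses at their efficiencies, weight (1-p_d) x_s,
* the dynamic pair: the two-state occupancy distribution over the window
  (pseudo-static deltas at E1, E2 plus the continuous exchange density),
  weight p_d,

and the photon-number distribution P(F) is taken empirically from the
data windows (standard PDA practice).  The expected histogram of
E_prox = N_R/F is then

    H(bin) = sum_F P(F) sum_{N_R in bin} sum_E P(E) Bin(N_R; F, eps(E)).

The binomial kernels depend only on the observed F values and the E grid,
so they are precomputed once per dataset; each model evaluation is a set
of small matrix-vector products, which keeps the global fit over several
window lengths fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .occupancy import occupancy_distribution

__all__ = ["PdaDataset", "PdaModel", "pda_histogram", "fit_pda"]

E_GRID_N = 501


def _eps_of_E(E, gamma: float = 1.0, alpha: float = 0.0):
    """Probability that a detected photon is red, given efficiency E."""
    g = 1.0 - E
    r = gamma * E + alpha * g
    return r / (g + r)


@dataclass
class PdaDataset:
    """Window photon counts of one window length, with precomputed kernels.

    ``F``/``n_red`` are the per-window totals; ``bin_edges`` the E-proximity
    histogram bins.  F values are stratified (grouped) to at most
    ``max_strata`` representative values to bound the kernel size.
    """

    T_ms: float
    F: np.ndarray
    n_red: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 41))
    max_strata: int = 60
    gamma: float = 1.0
    alpha: float = 0.0

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.int64)
        self.n_red = np.asarray(self.n_red, dtype=np.int64)
        if len(self.F) == 0:
            raise ValueError("empty photon-number distribution")
        self.E_grid = np.linspace(0.0, 1.0, E_GRID_N)
        self.hist = self._data_histogram()
        self._build_kernels()

    def _data_histogram(self):
        h, _ = np.histogram(self.n_red / self.F, bins=self.bin_edges)
        return h

    def _build_kernels(self):
        # stratify F by quantile to <= max_strata representative values
        Fs = np.sort(self.F)
        qs = np.linspace(0, 1, self.max_strata + 1)
        edges = np.unique(np.quantile(Fs, qs).astype(np.int64))
        idx = np.clip(np.searchsorted(edges, self.F, side="right") - 1,
                      0, len(edges) - 1)
        self.strata_F = np.array(
            [int(np.round(self.F[idx == k].mean())) for k in range(len(edges))
             if (idx == k).any()]
        )
        w = np.array([(idx == k).sum() for k in range(len(edges))
                      if (idx == k).any()], dtype=float)
        self.strata_w = w / w.sum()
        eps = _eps_of_E(self.E_grid, self.gamma, self.alpha)
        nb = len(self.bin_edges) - 1
        self.kernels = []
        for F in self.strata_F:
            nr = np.arange(F + 1)
            B = binom.pmf(nr[:, None], F, eps[None, :])  # (F+1, n_grid)
            bidx = np.clip(
                np.searchsorted(self.bin_edges, nr / F, side="right") - 1,
                0, nb - 1,
            )
            C = np.zeros((nb, E_GRID_N))
            np.add.at(C, bidx, B)
            self.kernels.append(C)


@dataclass
class PdaModel:
    """Static + binary-dynamic mixture over a common species set.

    ``E_species`` lists all species efficiencies; ``x_s`` their static
    fractions; ``dynamic_pair`` indexes the two exchanging species
    (state 1, state 2 of the occupancy theory); rates in ms^-1.
    """

    E_species: np.ndarray
    x_s: np.ndarray
    dynamic_pair: tuple
    k12: float
    k21: float
    p_d: float

    def efficiency_pmf(self, T_ms: float, E_grid: np.ndarray) -> np.ndarray:
        """P(E) on the grid (point masses folded onto nearest grid nodes)."""
        pmf = np.zeros_like(E_grid)

        def add_delta(E, w):
            i = int(np.clip(np.round(E * (len(E_grid) - 1)), 0, len(E_grid) - 1))
            pmf[i] += w

        for E_i, xs_i in zip(self.E_species, self.x_s):
            if xs_i > 0:
                add_delta(E_i, (1.0 - self.p_d) * xs_i)
        if self.p_d > 0:
            i1, i2 = self.dynamic_pair
            E1, E2 = self.E_species[i1], self.E_species[i2]
            occ = occupancy_distribution(self.k12, self.k21, T_ms, n_grid=1001)
            add_delta(E1, self.p_d * occ.w1)
            add_delta(E2, self.p_d * occ.w0)
            E_of_x = occ.x_grid * E1 + (1.0 - occ.x_grid) * E2
            idx = np.clip(
                np.round(E_of_x * (len(E_grid) - 1)).astype(int),
                0, len(E_grid) - 1,
            )
            np.add.at(pmf, idx, self.p_d * occ.xi * occ.dx)
        return pmf


def pda_histogram(model: PdaModel, data: PdaDataset) -> np.ndarray:
    """Expected E-proximity histogram (unit sum) for one window length."""
    pE = model.efficiency_pmf(data.T_ms, data.E_grid)
    h = np.zeros(len(data.bin_edges) - 1)
    for w, C in zip(data.strata_w, data.kernels):
        h += w * (C @ pE)
    s = h.sum()
    return h / s if s > 0 else h


def _pearson_chi2(model_h, data_h):
    n = data_h.sum()
    exp = np.clip(model_h * n, 1e-10, None)
    return float(((data_h - exp) ** 2 / np.clip(exp, 1.0, None)).sum())


def fit_pda(
    datasets,
    E_species,
    dynamic_pair,
    fit_static: bool = True,
    init=None,
    n_starts: int = 8,
    seed: int = 0,
    k_max: float = 50.0,
):
    """Global PDA fit across window lengths.

    Free parameters: ``p_d``, ``k12``, ``k21`` and (optionally) the static
    fractions.  Species efficiencies are held fixed (known from TCSPC /
    burst analysis, the standard workflow).  Multi-start simplex followed
    by a gradient polish; minimizes the summed Pearson chi^2.

    Returns a dict with ``p_d``, ``k12``, ``k21``, ``x_s``, per-window
    reduced chi^2 and the total.
    """
    from scipy.optimize import minimize

    E_species = np.asarray(E_species, dtype=float)
    n_sp = len(E_species)
    rng = np.random.default_rng(seed)

    def unpack(theta):
        p_d = 1.0 / (1.0 + np.exp(-theta[0]))
        k12 = np.exp(theta[1])
        k21 = np.exp(theta[2])
        if fit_static and n_sp > 1:
            g = np.concatenate((theta[3 : 3 + n_sp - 1], [0.0]))
            w = np.exp(g - g.max())
            x_s = w / w.sum()
        else:
            x_s = np.full(n_sp, 1.0 / n_sp)
        return p_d, k12, k21, x_s

    def objective(theta):
        p_d, k12, k21, x_s = unpack(theta)
        if not (1e-3 < k12 < k_max and 1e-3 < k21 < k_max):
            return 1e12
        model = PdaModel(
            E_species=E_species, x_s=x_s, dynamic_pair=dynamic_pair,
            k12=k12, k21=k21, p_d=p_d,
        )
        chi2 = 0.0
        for ds in datasets:
            chi2 += _pearson_chi2(pda_histogram(model, ds), ds.hist)
        return chi2

    n_par = 3 + (n_sp - 1 if fit_static and n_sp > 1 else 0)
    best = None
    for i in range(n_starts):
        if init is not None and i == 0:
            theta0 = np.asarray(init, dtype=float)
        else:
            theta0 = np.concatenate((
                [rng.uniform(-2, 2)],
                rng.uniform(np.log(0.5), np.log(20.0), 2),
                rng.uniform(-1, 1, n_par - 3),
            ))
        res = minimize(objective, theta0, method="Nelder-Mead",
                       options={"maxiter": 400 * n_par, "xatol": 1e-4,
                                "fatol": 1e-3})
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(objective, best.x, method="Nelder-Mead",
                      options={"maxiter": 800 * n_par, "xatol": 1e-6,
                               "fatol": 1e-6})
    if polish.fun < best.fun:
        best = polish
    p_d, k12, k21, x_s = unpack(best.x)
    model = PdaModel(E_species=E_species, x_s=x_s, dynamic_pair=dynamic_pair,
                     k12=k12, k21=k21, p_d=p_d)
    per_window = {}
    dof_tot, chi_tot = 0, 0.0
    for ds in datasets:
        c2 = _pearson_chi2(pda_histogram(model, ds), ds.hist)
        dof = max(int((ds.hist > 0).sum()) - n_par, 1)
        per_window[ds.T_ms] = c2 / dof
        chi_tot += c2
        dof_tot += dof
    return {
        "p_d": p_d, "k12": k12, "k21": k21, "x_s": x_s,
        "chi2_r": chi_tot / max(dof_tot, 1), "per_window_chi2_r": per_window,
        "model": model, "opt": best,
    }
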