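"""First-order kinetic networks: rate matrices, equilibria and spectra.

A conformational exchange between ``n`` states is modelled as a
continuous-time Markov chain with transition rate matrix ``K`` obeying the
convention

    K[i, j] = k_ij = rate of the transition  j -> i   (ms^-1,  i != j),

so that the master equation reads ``dx/dt = K x`` for the column vector of
state fractions ``x``.  Columns of ``K`` sum to zero; the diagonal holds the
negative total escape rate of each state.  An irreducible network has a
single zero eigenvalue whose right eigenvector is the equilibrium
distribution, and ``n - 1`` negative eigenvalues whose negative inverses are
the relaxation times observed in correlation experiments.

Units: rates in ms^-1, times in ms throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

__all__ = [
    "KineticNetwork",
    "EigenSystem",
    "build_rate_matrix",
    "equilibrium_fractions",
    "eigen_decompose",
    "mean_efficiency",
    "equilibrium_constant",
]

#: relative tolerance used to classify an eigenvalue as the stationary one
ZERO_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class KineticNetwork:
    """An ``n``-state first-order kinetic network.

    Attributes
    ----------
    K : ndarray, shape (n, n)
        Transition rate matrix in ms^-1, column-sum-zero convention
        ``K[i, j] =`` rate of ``j -> i``.
    state_labels : tuple of str
        Short state names, e.g. ``("HF", "MF", "LF")``.
    """

    K: np.ndarray
    state_labels: tuple = field(default=())

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be a square matrix")
        object.__setattr__(self, "K", K)
        if not self.state_labels:
            object.__setattr__(
                self, "state_labels", tuple(f"S{i + 1}" for i in range(K.shape[0]))
            )
        if len(self.state_labels) != K.shape[0]:
            raise ValueError("state_labels length must match K")
        off = K - np.diag(np.diag(K))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be nonnegative")
        colsum = K.sum(axis=0)
        scale = max(np.abs(K).max(), 1.0)
        if np.any(np.abs(colsum) > 1e-9 * scale):
            raise ValueError("columns of K must sum to zero")

    @property
    def n_states(self) -> int:
        return self.K.shape[0]

    def rate(self, frm: int | str, to: int | str) -> float:
        """Rate constant of the transition ``frm -> to`` in ms^-1."""
        j = self._index(frm)
        i = self._index(to)
        return float(self.K[i, j])

    def _index(self, state: int | str) -> int:
        if isinstance(state, str):
            return self.state_labels.index(state)
        return int(state)

    def is_irreducible(self) -> bool:
        return len(self.connected_components()) == 1

    def connected_components(self) -> list[list[int]]:
        """Strongly connected components of the transition graph."""
        adj = (np.abs(self.K) > 0).astype(int)
        np.fill_diagonal(adj, 0)
        n_comp, labels = scipy.sparse.csgraph.connected_components(
            adj, directed=True, connection="strong"
        )
        return [list(np.flatnonzero(labels == c)) for c in range(n_comp)]

    def detailed_balance_holds(self, rtol: float = 1e-8) -> bool:
        """True if ``x_i k_ji = x_j k_ij`` for all pairs at equilibrium."""
        if not self.is_irreducible():
            return False
        x = equilibrium_fractions(self)
        K = self.K
        n = self.n_states
        for i in range(n):
            for j in range(i + 1, n):
                fij = K[i, j] * x[j]  # flux j -> i
                fji = K[j, i] * x[i]
                if abs(fij - fji) > rtol * max(fij, fji, 1e-300):
                    return False
        return True


@dataclass(frozen=True)
class EigenSystem:
    """Spectral decomposition ``K = sum_l lambda^(l) Gamma^(l)``.

    ``eigenvalues[0] == 0`` (stationary mode); the remaining eigenvalues are
    sorted by decreasing relaxation time.  ``projectors[l]`` are the spectral
    projectors ``Gamma^(l)`` satisfying ``Gamma^(l) Gamma^(m) = delta_lm
    Gamma^(l)`` and ``sum_l Gamma^(l) = I``, so that
    ``exp(K t) = sum_l Gamma^(l) exp(lambda^(l) t)``.
    """

    eigenvalues: np.ndarray  # (n,), ms^-1, first entry 0
    projectors: np.ndarray  # (n, n, n)

    @property
    def relaxation_times(self) -> np.ndarray:
        """Relaxation times ``t_R^(l) = -1/lambda^(l)`` in ms, ``l >= 1``."""
        lam = self.eigenvalues[1:]
        return -1.0 / lam

    def propagator(self, t: float | np.ndarray) -> np.ndarray:
        """``exp(K t)`` from the spectral representation.

        For scalar ``t`` returns (n, n); for an array of times returns
        (len(t), n, n).
        """
        t = np.asarray(t, dtype=float)
        weights = np.exp(np.multiply.outer(t, self.eigenvalues))  # (..., n)
        return np.tensordot(weights, self.projectors, axes=([-1], [0]))


def build_rate_matrix(
    n: int,
    rates: Mapping[tuple, float],
    state_labels: Sequence[str] | None = None,
) -> KineticNetwork:
    """Assemble a :class:`KineticNetwork` from a map of pairwise rates.

    Parameters
    ----------
    n : int
        Number of states.
    rates : mapping
        ``{(j, i): k}`` with ``k`` the rate of the transition ``j -> i`` in
        ms^-1.  States may be 0-based indices or labels from
        ``state_labels``.  Unspecified pairs default to zero.
    """
    labels = tuple(state_labels) if state_labels else tuple(f"S{i + 1}" for i in range(n))
    if len(labels) != n:
        raise ValueError("state_labels length must equal n")

    def idx(s):
        if isinstance(s, str):
            if s not in labels:
                raise ValueError(f"unknown state label {s!r}")
            return labels.index(s)
        s = int(s)
        if not 0 <= s < n:
            raise ValueError(f"state index {s} out of range for n={n}")
        return s

    K = np.zeros((n, n))
    for (frm, to), k in rates.items():
        j, i = idx(frm), idx(to)
        if i == j:
            raise ValueError(f"self-transition {frm}->{to} is not allowed")
        k = float(k)
        if k < 0:
            raise ValueError(f"negative rate {k} for {frm}->{to}")
        K[i, j] = k
    np.fill_diagonal(K, 0.0)
    K -= np.diag(K.sum(axis=0))
    return KineticNetwork(K=K, state_labels=labels)


def equilibrium_fractions(net: KineticNetwork) -> np.ndarray:
    """Stationary state fractions ``x_d`` with ``K x_d = 0`` and ``sum = 1``.

    Raises ``ValueError`` naming the disconnected groups if the network is
    reducible (the stationary distribution would not be unique).
    """
    comps = net.connected_components()
    if len(comps) > 1:
        groups = ", ".join(
            "{" + ",".join(net.state_labels[i] for i in c) + "}" for c in comps
        )
        raise ValueError(f"network is reducible; disconnected state groups: {groups}")
    ns = scipy.linalg.null_space(net.K, rcond=1e-10)
    if ns.shape[1] != 1:  # pragma: no cover - guarded by irreducibility
        raise ValueError("stationary distribution is not unique")
    x = ns[:, 0]
    x = x / x.sum()
    if np.any(x < -1e-10):
        raise ValueError("stationary solution has negative entries")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


def _sorted_system(lam: np.ndarray, gammas: np.ndarray, scale: float):
    """Order modes: stationary first, then decreasing relaxation time."""
    tol = ZERO_EIG_RTOL * max(scale, 1.0)
    zero = np.abs(lam) < tol
    if zero.sum() != 1:
        raise ValueError(
            f"expected exactly one zero eigenvalue, found {int(zero.sum())} "
            "(network may be reducible)"
        )
    i0 = int(np.flatnonzero(zero)[0])
    rest = [i for i in range(len(lam)) if i != i0]
    rest.sort(key=lambda i: abs(lam[i]))  # slowest (longest t_R) first
    order = [i0] + rest
    lam = lam[order].copy()
    lam[0] = 0.0
    return EigenSystem(eigenvalues=lam, projectors=gammas[order])


def eigen_decompose(net: KineticNetwork) -> EigenSystem:
    """Spectral decomposition of the rate matrix.

    When detailed balance holds, the decomposition goes through the
    symmetrized matrix ``S^-1 K S`` with ``S = diag(sqrt(x_d))``, which is
    symmetric and guarantees a real spectrum and orthogonal modes; otherwise
    a general eigensolver is used and complex pairs are rejected beyond
    tolerance.
    """
    K = net.K
    n = net.n_states
    scale = np.abs(K).max()
    if scale == 0.0:
        raise ValueError(
            "rate matrix is identically zero (fully static); "
            "no unique stationary mode exists"
        )
    if net.is_irreducible() and net.detailed_balance_holds():
        x = equilibrium_fractions(net)
        s = np.sqrt(np.clip(x, 1e-300, None))
        Ksym = (K * s[None, :]) / s[:, None] * 0.5
        Ksym = Ksym + Ksym.T  # symmetrize away rounding noise
        lam, U = np.linalg.eigh(Ksym)
        # right eigvec v = s*u, left w = u/s; Gamma = v w^T (u orthonormal)
        gammas = np.empty((n, n, n))
        for l in range(n):
            u = U[:, l]
            gammas[l] = np.outer(s * u, u / s)
        return _sorted_system(lam, gammas, scale)

    lam, VL, VR = scipy.linalg.eig(K, left=True, right=True)
    if np.abs(lam.imag).max() > 1e-8 * scale:
        raise ValueError(
            "rate matrix has a substantially complex spectrum; "
            "use a detailed-balance (symmetrizable) network"
        )
    lam = lam.real
    gammas = np.empty((n, n, n))
    for l in range(n):
        v = VR[:, l].real
        w = VL[:, l].real
        denom = w @ v
        if abs(denom) < 1e-12:
            raise ValueError(
                "defective rate matrix (non-diagonalizable beyond tolerance); "
                "consider the symmetrized solver via a detailed-balance network"
            )
        gammas[l] = np.outer(v, w) / denom
    return _sorted_system(lam, gammas, scale)


def mean_efficiency(x, E) -> float:
    """Fraction-weighted mean FRET efficiency ``<E> = sum_i x_i E_i``."""
    x = np.asarray(x, dtype=float)
    E = np.asarray(E, dtype=float)
    if x.shape != E.shape:
        raise ValueError("fractions and efficiencies must have equal length")
    if abs(x.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    return float(x @ E)


def equilibrium_constant(net: KineticNetwork) -> float:
    """Two-state equilibrium constant ``K_eq = x_d(2)/x_d(1) = k21/k12``."""
    if net.n_states != 2:
        raise ValueError("equilibrium constant is defined for two-state networks")
    x = equilibrium_fractions(net)
    return float(x[1] / x[0])
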