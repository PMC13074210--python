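"""Static and dynamic FRET-lines for ideal (linker-free) dyes.

In a two-dimensional burst histogram of intensity-based FRET efficiency E
against the intensity-weighted mean donor lifetime <tau_DA>_F, a molecule
with a single fixed transfer efficiency falls on the *static line*

    E = 1 - <tau_DA>_F / tau_D0 ,

while a molecule mixing two species with efficiencies E1, E2 during its
transit traces the *dynamic line*: the efficiency averages linearly in the
occupancy x of state 1, but the fluorescence-weighted lifetime averages as a
ratio of the second to the first moment of the lifetime distribution,
pulling the curve above the static line.  The perpendicular displacement in
normalized coordinates (tau/tau_D0, E) is the *dynamic shift* ds, a
model-free indicator of exchange.

The moment representation (m1, m2) = (1 - E, (1 - E)(1 - E_tau)) maps both
moments to affine functions of x, so binary dynamic lines become straight —
convenient for reading mixing ratios off a histogram.

The excess of E over the lifetime-based efficiency E_tau = 1 - tau/tau_D0
carries the within-burst variance of E:  Var(E) = (1 - E)(E - E_tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FretIndicators",
    "DynamicShiftCurve",
    "static_line",
    "dynamic_line",
    "dynamic_shift",
    "max_dynamic_shift",
    "variance_from_indicators",
    "moment_coordinates",
]


@dataclass(frozen=True)
class FretIndicators:
    """Burst-averaged FRET indicators of a single-molecule event.

    ``E`` is the intensity-based efficiency, ``tau_F`` the
    intensity-weighted mean donor lifetime <tau_DA>_F in ns and ``tau_D0``
    the donor-only lifetime in ns.
    """

    E: float
    tau_F: float
    tau_D0: float

    @property
    def E_tau(self) -> float:
        """Lifetime-based efficiency ``1 - <tau_DA>_F / tau_D0``."""
        return 1.0 - self.tau_F / self.tau_D0


@dataclass(frozen=True)
class DynamicShiftCurve:
    """Dynamic shift ds(x) sampled over a grid of occupancies of state 1."""

    E1: float
    E2: float
    x_grid: np.ndarray
    ds: np.ndarray
    ds_max: float
    x_max: float


def static_line(tau_D0: float, n: int = 201):
    """The static FRET-line as arrays ``(tau_F, E)``.

    Runs from (tau_D0, 0) to (0, 1):  E = 1 - tau/tau_D0.
    """
    if tau_D0 <= 0:
        raise ValueError("tau_D0 must be positive")
    tau = np.linspace(tau_D0, 0.0, n)
    return tau, 1.0 - tau / tau_D0


def _mixture_indicators(x, E1, E2, tau_D0):
    """(E, <tau_DA>_F) of an ideal binary mixture at occupancy ``x``."""
    x = np.asarray(x, dtype=float)
    tau1 = tau_D0 * (1.0 - E1)
    tau2 = tau_D0 * (1.0 - E2)
    m1 = x * tau1 + (1.0 - x) * tau2
    m2 = x * tau1**2 + (1.0 - x) * tau2**2
    E = x * E1 + (1.0 - x) * E2
    return E, m2 / m1


def dynamic_line(E1: float, E2: float, tau_D0: float, x_grid=None):
    """Binary dynamic FRET-line.

    Returns ``(x, E, tau_F)``: species fraction of state 1, mean efficiency
    E(x) and intensity-weighted mean lifetime
    ``<tau_DA>_F = (x tau1^2 + (1-x) tau2^2) / (x tau1 + (1-x) tau2)``.
    """
    for E in (E1, E2):
        if not 0.0 <= E < 1.0:
            raise ValueError("efficiencies must lie in [0, 1)")
    if E1 == E2:
        raise ValueError("E1 and E2 must differ")
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 201)
    x = np.asarray(x_grid, dtype=float)
    E, tau_F = _mixture_indicators(x, E1, E2, tau_D0)
    return x, E, tau_F


def dynamic_shift(x, E1: float, E2: float):
    """Dynamic shift of a binary mixture at occupancy ``x`` of state 1.

        ds(x) = (1/2) (E2 - E1)^2 x (1 - x) / [x (1 - E1) + (1 - x)(1 - E2)]

    This equals the perpendicular distance of the dynamic-line point from
    the static line in normalized (tau/tau_D0, E) coordinates.
    """
    if E1 >= 1.0 or E2 >= 1.0:
        raise ValueError("efficiencies must be < 1")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    num = 0.5 * (E2 - E1) ** 2 * x * (1.0 - x)
    den = x * (1.0 - E1) + (1.0 - x) * (1.0 - E2)
    return num / den


def max_dynamic_shift(E1: float, E2: float):
    """Closed-form maximum of the dynamic shift and its argmax.

        ds_max = (1/2) (sqrt(1 - E1) - sqrt(1 - E2))^2
        x_max  = sqrt(1 - E2) / (sqrt(1 - E1) + sqrt(1 - E2))
    """
    for E in (E1, E2):
        if not 0.0 <= E < 1.0:
            raise ValueError("efficiencies must lie in [0, 1)")
    r1 = np.sqrt(1.0 - E1)
    r2 = np.sqrt(1.0 - E2)
    ds_max = 0.5 * (r1 - r2) ** 2
    x_max = r2 / (r1 + r2)
    return float(ds_max), float(x_max)


def dynamic_shift_curve(E1: float, E2: float, n: int = 501) -> DynamicShiftCurve:
    x = np.linspace(0.0, 1.0, n)
    ds = dynamic_shift(x, E1, E2)
    ds_max, x_max = max_dynamic_shift(E1, E2)
    return DynamicShiftCurve(E1=E1, E2=E2, x_grid=x, ds=ds, ds_max=ds_max, x_max=x_max)


def variance_from_indicators(ind: FretIndicators, warn_unphysical: bool = True):
    """Within-burst FRET-efficiency variance ``Var(E) = (1-E)(E - E_tau)``.

    For a physical species mixture E >= E_tau and the value is nonnegative;
    shot noise or linker artifacts can push E below E_tau, which is flagged
    (the raw, possibly negative, value is still returned).
    """
    var = (1.0 - ind.E) * (ind.E - ind.E_tau)
    if warn_unphysical and var < -1e-9:
        import warnings

        warnings.warn(
            "E < E_tau: unphysical indicator pair (shot noise or linker "
            "artifacts); returning negative variance",
            stacklevel=2,
        )
    return var


def moment_coordinates(E, E_tau):
    """Moment representation ``(m1, m2) = (1 - E, (1 - E)(1 - E_tau))``.

    Both coordinates are affine in the occupancy of a binary mixture, so
    dynamic lines plot as straight segments in this plane.
    """
    E = np.asarray(E, dtype=float)
    E_tau = np.asarray(E_tau, dtype=float)
    m1 = 1.0 - E
    m2 = (1.0 - E) * (1.0 - E_tau)
    return m1, m2
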