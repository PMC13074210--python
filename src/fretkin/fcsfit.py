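"""Model fitting of correlation curves.

Fits the standard product model

    G(t_c) = 1/N * G_diff(t_c; t_diff, s) * (1 + sum_l A_l e^{-t_c/t_R,l}) + 1 + c

to measured auto-/cross-correlation curves, singly or globally (shared
relaxation times and diffusion time across a set of curves, amplitudes
free per curve).  The additive constant ``c`` absorbs the small negative
baseline offset that closed-box simulations (fixed molecule number)
produce, as well as instrumental baseline drifts in real data.
"""

from __future__ import annotations

import numpy as np

from .fcsmodel import CorrelationCurve, diffusion_term

__all__ = ["fit_correlation", "fit_correlations_global"]


def _model_single(t, a0, t_diff, s, amps, t_rs, offset):
    kin = np.full_like(t, a0)
    for A, tr in zip(amps, t_rs):
        kin = kin + A * np.exp(-t / tr)
    return 1.0 + diffusion_term(t, t_diff, s) * kin + offset


def fit_correlation(
    curve: CorrelationCurve,
    n_relaxations: int = 0,
    s: float = 0.25,
    t_diff_init: float = 2.0,
    t_R_init=None,
    lag_min: float = 0.0,
    lag_max: float = np.inf,
    with_offset: bool = True,
    fix_t_diff: float | None = None,
    fix_offset: float | None = None,
    sigma_floor_frac: float = 0.1,
):
    """Fit one correlation curve; returns an lmfit result.

    Parameters of the result: ``a0`` (diffusion amplitude, 1/N for an
    autocorrelation), ``t_diff``, offset ``c`` and per relaxation the
    signed amplitude ``a1..`` and time ``tR1..`` (ms).
    """
    return fit_correlations_global(
        [curve],
        n_relaxations=n_relaxations,
        s=s,
        t_diff_init=t_diff_init,
        t_R_init=t_R_init,
        lag_min=lag_min,
        lag_max=lag_max,
        with_offset=with_offset,
        fix_t_diff=fix_t_diff,
        fix_offset=fix_offset,
        sigma_floor_frac=sigma_floor_frac,
    )


def fit_correlations_global(
    curves,
    n_relaxations: int = 1,
    s: float = 0.25,
    t_diff_init: float = 2.0,
    t_R_init=None,
    lag_min: float = 0.0,
    lag_max: float = np.inf,
    with_offset: bool = True,
    fix_t_diff: float | None = None,
    fix_offset: float | None = None,
    sigma_floor_frac: float = 0.1,
):
    """Global fit of several curves with shared ``t_diff`` and ``t_R`` set.

    The model per curve is ``1 + G_diff(t) (a0 + sum_l a_l e^{-t/tR_l}) + c``
    with signed amplitudes (species cross-correlations can have negative
    plateaus); the relaxation times ``tR{l}`` and the diffusion time are
    shared, as appropriate for species or channel correlations of one
    measurement.  ``a{i}_0`` is the diffusion-scale amplitude of curve i
    (equals (1 + A0)/N for a color correlation).

    Result attributes: ``params`` plus ``t_R`` (sorted ascending, ms) and
    ``redchi``.
    """
    import lmfit

    if n_relaxations >= 1 and t_R_init is None:
        t_R_init = np.geomspace(0.05, 0.5, n_relaxations)
    params = lmfit.Parameters()
    params.add(
        "t_diff",
        value=fix_t_diff if fix_t_diff is not None else t_diff_init,
        min=1e-3,
        max=1e3,
        vary=fix_t_diff is None,
    )
    for l in range(n_relaxations):
        params.add(f"tR{l + 1}", value=float(t_R_init[l]), min=1e-4, max=50.0)
    for i, c in enumerate(curves):
        G0 = float(np.clip(c.G.max() - 1.0, -5.0, 50.0))
        params.add(f"a{i}_0", value=G0 if abs(G0) > 1e-3 else 0.1,
                   min=-10.0, max=100.0)
        if fix_offset is not None:
            params.add(f"c{i}", value=fix_offset, vary=False)
        else:
            params.add(f"c{i}", value=0.0, min=-0.5, max=0.5, vary=with_offset)
        for l in range(n_relaxations):
            params.add(f"a{i}_{l + 1}", value=0.1, min=-50.0, max=50.0)

    masks = [(c.lag >= lag_min) & (c.lag <= lag_max) for c in curves]
    # block-wise sigma systematically underestimates the (correlated) noise
    # at long lags; a floor relative to the per-curve median keeps those
    # points from dominating the fit
    sigmas = []
    for c, msk in zip(curves, masks):
        if c.sigma is None:
            sigmas.append(np.ones(msk.sum()))
        else:
            sg = c.sigma[msk].copy()
            floor = sigma_floor_frac * np.median(sg)
            sigmas.append(np.maximum(sg, floor))

    def resid(p):
        out = []
        t_rs = [p[f"tR{l + 1}"] for l in range(n_relaxations)]
        for i, c in enumerate(curves):
            t = c.lag[masks[i]]
            amps = [p[f"a{i}_{l + 1}"] for l in range(n_relaxations)]
            m = _model_single(
                t, p[f"a{i}_0"], p["t_diff"], s, amps, t_rs, p[f"c{i}"]
            )
            out.append((c.G[masks[i]] - m) / sigmas[i])
        return np.concatenate(out)

    res = lmfit.minimize(resid, params, method="least_squares")
    t_R = np.sort([res.params[f"tR{l + 1}"].value for l in range(n_relaxations)])
    res.t_R = t_R
    return res
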