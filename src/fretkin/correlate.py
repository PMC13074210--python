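"""Multi-tau correlation of binned photon streams.

Photon arrival times (optionally carrying per-photon weights, as in
filtered-FCS) are binned at a base resolution and correlated with the
classic multi-tau scheme: a cascade of lag registers whose bin width
doubles every half-cascade, giving quasi-logarithmic lag coverage from the
base bin width up to seconds at O(n log n) cost.  Normalization is
symmetric: G(k) = <a_i b_{i+k}> / (<a_i> <b_{i+k}>), with the averages
taken over the overlapping segments.

Uncertainties are estimated by splitting the measurement into contiguous
time blocks, correlating each block independently, and taking the standard
error across blocks (wise/block-bootstrap estimate).
"""

from __future__ import annotations

import numpy as np

from .fcsmodel import CorrelationCurve

__all__ = ["bin_photons", "multitau", "correlate_photons"]


def bin_photons(times_ms, duration_ms: float, bin_ms: float, weights=None):
    """Bin photon arrival times into a uniform intensity trace.

    Returns a float array of (weighted) counts per bin of width ``bin_ms``.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    n = int(np.ceil(duration_ms / bin_ms))
    idx = np.minimum((times_ms / bin_ms).astype(np.int64), n - 1)
    return np.bincount(idx, weights=weights, minlength=n).astype(float)


def multitau(a, b, bin_ms: float, m: int = 16, min_len: int = 64):
    """Multi-tau correlation of two binned traces.

    Parameters
    ----------
    a, b : arrays
        Intensity traces on a common uniform grid of width ``bin_ms``.
    m : int
        Lags per cascade (halved after the first cascade before the bin
        width doubles).

    Returns
    -------
    (lags_ms, G) with G normalized to 1 at no correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must share a grid")
    lags, G = [], []
    dt = bin_ms
    cascade = 0
    while len(a) >= min_len:
        ks = range(1, m + 1) if cascade == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            n = len(a) - k
            if n < min_len:
                break
            ma = a[:n].mean()
            mb = b[k:].mean()
            if ma <= 0 or mb <= 0:
                continue
            G.append(float(a[:n] @ b[k:]) / n / (ma * mb))
            lags.append(k * dt)
        # coarsen by 2 (average keeps the normalization scale-free)
        ncut = (len(a) // 2) * 2
        a = 0.5 * (a[:ncut:2] + a[1:ncut:2])
        b = 0.5 * (b[:ncut:2] + b[1:ncut:2])
        dt *= 2.0
        cascade += 1
    return np.asarray(lags), np.asarray(G)


def correlate_photons(
    times_a,
    times_b,
    duration_ms: float,
    bin_ms: float = 0.002,
    weights_a=None,
    weights_b=None,
    n_blocks: int = 16,
    m: int = 16,
    pair: str = "",
) -> CorrelationCurve:
    """Correlate two photon streams with block-wise error estimates.

    ``times_a``/``times_b`` are macro times in ms (possibly the same
    array for an autocorrelation); optional per-photon ``weights`` implement
    filtered-FCS species correlations.  The trace is split into
    ``n_blocks`` contiguous blocks; G and sigma are the across-block mean
    and standard error on the common lag grid.
    """
    a = bin_photons(times_a, duration_ms, bin_ms, weights_a)
    b = bin_photons(times_b, duration_ms, bin_ms, weights_b)
    nb = len(a) // n_blocks
    if nb < 256:
        raise ValueError("stream too short for the requested block count")
    curves = []
    for i in range(n_blocks):
        seg = slice(i * nb, (i + 1) * nb)
        lags, G = multitau(a[seg], b[seg], bin_ms, m=m)
        curves.append(G)
    nmin = min(len(c) for c in curves)
    lags = lags[:nmin]
    Gs = np.vstack([c[:nmin] for c in curves])
    G = Gs.mean(axis=0)
    sigma = Gs.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    sigma = np.clip(sigma, 1e-12, None)
    return CorrelationCurve(lag=lags, G=G, sigma=sigma, pair=pair,
                            meta={"bin_ms": bin_ms, "n_blocks": n_blocks})
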