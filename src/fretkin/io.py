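"""File formats: TSV tables with ``#`` header metadata, YAML configs.

All tabular artifacts (correlation curves, decay histograms, burst tables,
FRET-lines, densities) are tab-separated text with a small ``# key: value``
metadata header; rate matrices and simulation settings round-trip through
a structured YAML config.  Photon streams can be exported as TSV (three
columns) or cached as ``.npz`` for scratch use.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fcsmodel import CorrelationCurve
from .kinetics import KineticNetwork
from .simulate import BurstTable, PhotonStream
from .tcspc import DecayHistogram

__all__ = [
    "write_curve", "read_curve",
    "write_decay", "read_decay",
    "write_bursts", "read_bursts",
    "network_to_config", "network_from_config",
    "save_network", "load_network",
    "stream_to_tsv", "stream_from_tsv",
    "save_stream_npz", "load_stream_npz",
    "provenance",
]


def _write_tsv(path, df: pd.DataFrame, meta: dict):
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_tsv(path):
    path = Path(path)
    meta = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_curve(path, curve: CorrelationCurve):
    df = pd.DataFrame({
        "lag_ms": curve.lag,
        "G": curve.G,
        "sigma": curve.sigma if curve.sigma is not None else np.nan,
    })
    _write_tsv(path, df, {"type": "correlation", "pair": curve.pair})


def read_curve(path) -> CorrelationCurve:
    df, meta = _read_tsv(path)
    sigma = df["sigma"].to_numpy()
    if np.all(np.isnan(sigma)):
        sigma = None
    return CorrelationCurve(
        lag=df["lag_ms"].to_numpy(), G=df["G"].to_numpy(),
        sigma=sigma, pair=meta.get("pair", ""),
    )


def write_decay(path, hist: DecayHistogram):
    df = pd.DataFrame({"t_ns": hist.t, "counts": hist.counts})
    width = hist.bin_edges[1] - hist.bin_edges[0]
    _write_tsv(path, df, {"type": "decay", "bin_width_ns": width})


def read_decay(path) -> DecayHistogram:
    df, meta = _read_tsv(path)
    t = df["t_ns"].to_numpy()
    w = float(meta.get("bin_width_ns", t[1] - t[0]))
    edges = np.concatenate((t - w / 2, [t[-1] + w / 2]))
    return DecayHistogram(bin_edges=edges, counts=df["counts"].to_numpy())


def write_bursts(path, bursts: BurstTable):
    _write_tsv(path, bursts.to_dataframe(), {"type": "bursts", **{
        k: v for k, v in bursts.meta.items() if np.isscalar(v)
    }})


def read_bursts(path) -> BurstTable:
    df, meta = _read_tsv(path)
    return BurstTable(
        start_ms=df["start_ms"].to_numpy(),
        stop_ms=df["stop_ms"].to_numpy(),
        n_green=df["n_green"].to_numpy(dtype=int),
        n_red=df["n_red"].to_numpy(dtype=int),
        E=df["E"].to_numpy(),
        tau_F_ns=df["tau_F_ns"].to_numpy(),
        meta=meta,
    )


def network_to_config(net: KineticNetwork) -> dict:
    """Serialize a rate matrix as labels + ``from,to,rate_per_ms`` triples.

    The convention ``K[i, j] =`` rate j -> i is stated in the config to
    keep files self-describing.
    """
    triples = []
    n = net.n_states
    for j in range(n):
        for i in range(n):
            if i != j and net.K[i, j] != 0:
                triples.append(
                    f"{net.state_labels[j]},{net.state_labels[i]},{net.K[i, j]:.10g}"
                )
    return {
        "state_labels": list(net.state_labels),
        "rates": triples,
        "convention": "rate entries are from,to,rate_per_ms; K[i,j] = rate j->i",
    }


def network_from_config(cfg: dict) -> KineticNetwork:
    from .kinetics import build_rate_matrix

    labels = cfg["state_labels"]
    rates = {}
    for triple in cfg["rates"]:
        frm, to, k = (x.strip() for x in triple.split(","))
        rates[(frm, to)] = float(k)
    return build_rate_matrix(len(labels), rates, state_labels=labels)


def save_network(path, net: KineticNetwork):
    Path(path).write_text(yaml.safe_dump(network_to_config(net)))


def load_network(path) -> KineticNetwork:
    return network_from_config(yaml.safe_load(Path(path).read_text()))


def stream_to_tsv(path, stream: PhotonStream):
    df = pd.DataFrame({
        "macro_ms": stream.macro_ms,
        "channel": stream.channel,
        "micro_ns": stream.micro_ns,
    })
    _write_tsv(path, df, {"type": "photons",
                          "duration_ms": stream.duration_ms})


def stream_from_tsv(path) -> PhotonStream:
    df, meta = _read_tsv(path)
    return PhotonStream(
        macro_ms=df["macro_ms"].to_numpy(),
        channel=df["channel"].to_numpy(dtype=np.uint8),
        micro_ns=df["micro_ns"].to_numpy(dtype=np.float32),
        duration_ms=float(meta["duration_ms"]),
    )


def save_stream_npz(path, stream: PhotonStream):
    np.savez_compressed(
        path, macro_ms=stream.macro_ms, channel=stream.channel,
        micro_ns=stream.micro_ns, duration_ms=stream.duration_ms,
    )


def load_stream_npz(path) -> PhotonStream:
    d = np.load(path)
    return PhotonStream(
        macro_ms=d["macro_ms"], channel=d["channel"],
        micro_ns=d["micro_ns"], duration_ms=float(d["duration_ms"]),
    )


def provenance(config: dict, seed) -> dict:
    """Provenance block written alongside every stochastic CLI output."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
        "seed": int(seed) if seed is not None else None,
    }
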