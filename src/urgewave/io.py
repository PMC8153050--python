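"""HDF5 containers for epoch sets and ERSP tensors.

One file can hold several named objects (one HDF5 group each); per-epoch /
per-unit metadata tables travel as JSON attributes so the files remain
self-describing.
"""

from __future__ import annotations

from io import StringIO

import h5py
import numpy as np
import pandas as pd

from .ersp import ERSPTensor
from .preprocess import EpochSet


def _meta_to_attr(df: pd.DataFrame) -> str:
    return df.to_json(orient="split")


def _meta_from_attr(s: str) -> pd.DataFrame:
    return pd.read_json(StringIO(s), orient="split")


def save_epochs_h5(path, epoch_sets: dict) -> None:
    """Write named :class:`EpochSet` objects to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        for name, es in epoch_sets.items():
            g = fh.create_group(str(name))
            g.create_dataset("data", data=es.data, compression="gzip")
            g.create_dataset("times", data=es.times)
            g.attrs["fs"] = es.fs
            g.attrs["window"] = es.window
            g.attrs["pad_s"] = es.pad_s
            g.attrs["baseline"] = es.baseline
            g.attrs["n_excluded"] = es.n_excluded
            g.attrs["metadata"] = _meta_to_attr(es.metadata)


def load_epochs_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for name, g in fh.items():
            out[name] = EpochSet(
                data=g["data"][()],
                times=g["times"][()],
                fs=float(g.attrs["fs"]),
                metadata=_meta_from_attr(g.attrs["metadata"]),
                window=tuple(g.attrs["window"]),
                pad_s=float(g.attrs["pad_s"]),
                baseline=tuple(g.attrs["baseline"]),
                n_excluded=int(g.attrs["n_excluded"]),
            )
    return out


def save_ersp_h5(path, tensors: dict) -> None:
    """Write named :class:`ERSPTensor` objects to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        for name, t in tensors.items():
            g = fh.create_group(str(name))
            g.create_dataset("values", data=t.values, compression="gzip")
            g.create_dataset("freqs", data=t.freqs)
            g.create_dataset("times", data=t.times)
            g.attrs["units"] = _meta_to_attr(t.units)


def load_ersp_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for name, g in fh.items():
            out[name] = ERSPTensor(
                values=g["values"][()],
                freqs=g["freqs"][()],
                times=g["times"][()],
                units=_meta_from_attr(g.attrs["units"]),
            )
    return out


def write_dipoles_tsv(path, dipoles, labels=None) -> None:
    """Dipole table: ic_id, subject, x, y, z (+ true cluster when known)."""
    df = pd.DataFrame(
        {
            "ic_id": np.arange(dipoles.coordinates.shape[0]),
            "subject": dipoles.subject,
            "x": dipoles.coordinates[:, 0],
            "y": dipoles.coordinates[:, 1],
            "z": dipoles.coordinates[:, 2],
        }
    )
    if labels is not None:
        df["true_cluster"] = labels
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_dipoles_tsv(path):
    from .synthetic import DipoleSet

    df = pd.read_csv(path, sep="\t")
    dip = DipoleSet(
        coordinates=df[["x", "y", "z"]].to_numpy(dtype=float),
        subject=df["subject"].to_numpy(),
    )
    labels = df["true_cluster"].to_numpy() if "true_cluster" in df else None
    return dip, labels
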