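"""HDF5 and delimited-text persistence of pipeline artifacts.

Layout conventions:

* subject containers:   /subjects/<id>/signals  (ROIs x samples),
  attrs fs, label, seed; /subjects/<id>/schedule when ground truth exists.
* connectivity graphs:  /dfcg/strength and /dfcg/mode  (W x N x N),
  window grid and band table stored as attributes.
* eigenvalue series:    /nmts/lambda  (N x W) with subject attributes.
* codebooks:            /codebook/prototypes plus hyperparameter attrs.

Index files and exports are plain tab-separated text via pandas.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .coupling import CouplingSnapshot
from .graphs import EigenTimeSeries
from .microstates import Codebook
from .spectral import WindowGrid
from .synthetic import Subject

__all__ = [
    "write_subjects",
    "read_subject_signals",
    "write_index",
    "write_dfcg",
    "read_dfcg",
    "write_eigen",
    "read_eigen",
    "export_eigen_text",
    "write_codebook",
    "read_codebook",
    "export_symbolic_text",
    "read_signals_text",
]


def write_subjects(path, subjects: list[Subject]) -> None:
    """Write simulated subjects (signals + ground-truth schedule) to HDF5."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("subjects")
        for sub in subjects:
            g = grp.create_group(sub.subject_id)
            g.create_dataset("signals", data=sub.signals)
            g.attrs["fs"] = sub.fs
            g.attrs["label"] = sub.label
            g.attrs["seed"] = sub.seed
            if sub.ground_truth is not None:
                g.create_dataset("schedule", data=sub.ground_truth.schedule)
                g.attrs["segment_samples"] = \
                    sub.ground_truth.segment_samples


def read_subject_signals(path, subject_id: str
                         ) -> tuple[np.ndarray, float, str]:
    """Read one subject's (signals, fs, label) from a subject container."""
    with h5py.File(path, "r") as f:
        g = f[f"subjects/{subject_id}"]
        return g["signals"][...], float(g.attrs["fs"]), str(g.attrs["label"])


def list_subjects(path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f["subjects"].keys())


def write_index(path, subjects: list[Subject]) -> None:
    """Tab-separated subject index: subject_id, label, seed."""
    df = pd.DataFrame({"subject_id": [s.subject_id for s in subjects],
                       "label": [s.label for s in subjects],
                       "seed": [s.seed for s in subjects]})
    df.to_csv(path, sep="\t", index=False)


def _band_table(bands) -> np.ndarray:
    return np.array([(b.name, b.low, b.high) for b in bands],
                    dtype=[("name", "S16"), ("low", "f8"), ("high", "f8")])


def write_dfcg(path, snapshots: list[CouplingSnapshot], grid: WindowGrid,
               bands) -> None:
    strength = np.stack([s.strength for s in snapshots])
    mode = np.stack([s.mode for s in snapshots])
    with h5py.File(path, "w") as f:
        g = f.create_group("dfcg")
        g.create_dataset("strength", data=strength)
        g.create_dataset("mode", data=mode)
        g.attrs["fs"] = grid.fs
        g.attrs["width"] = grid.width
        g.attrs["step"] = grid.step
        g.attrs["width_samples"] = grid.width_samples
        g.create_dataset("window_starts", data=grid.starts)
        g.create_dataset("bands", data=_band_table(bands))


def read_dfcg(path) -> tuple[list[CouplingSnapshot], WindowGrid]:
    with h5py.File(path, "r") as f:
        g = f["dfcg"]
        strength = g["strength"][...]
        mode = g["mode"][...]
        grid = WindowGrid(fs=float(g.attrs["fs"]),
                          width=float(g.attrs["width"]),
                          step=float(g.attrs["step"]),
                          starts=g["window_starts"][...],
                          width_samples=int(g.attrs["width_samples"]))
    snaps = [CouplingSnapshot(window_id=w, strength=strength[w],
                              mode=mode[w]) for w in range(strength.shape[0])]
    return snaps, grid


def write_eigen(path, ets: EigenTimeSeries) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("nmts")
        g.create_dataset("lambda", data=ets.values)
        if ets.subject_id is not None:
            g.attrs["subject_id"] = ets.subject_id


def read_eigen(path) -> EigenTimeSeries:
    with h5py.File(path, "r") as f:
        g = f["nmts"]
        sid = g.attrs.get("subject_id")
        return EigenTimeSeries(values=g["lambda"][...],
                               subject_id=None if sid is None else str(sid))


def export_eigen_text(path, ets: EigenTimeSeries) -> None:
    """Eigenvalue series as TSV: rows = eigenvalue rank, columns = windows."""
    pd.DataFrame(ets.values).to_csv(path, sep="\t", index=False,
                                    header=False)


def write_codebook(path, codebook: Codebook) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("codebook")
        g.create_dataset("prototypes", data=codebook.prototypes)
        g.create_dataset("distortion_curve", data=codebook.distortion_curve)
        g.attrs["distortion"] = codebook.distortion
        if codebook.label is not None:
            g.attrs["label"] = codebook.label
        if codebook.seed is not None:
            g.attrs["seed"] = codebook.seed
        g.attrs["hyperparameters"] = json.dumps(codebook.hyperparameters)


def read_codebook(path) -> Codebook:
    with h5py.File(path, "r") as f:
        g = f["codebook"]
        label = g.attrs.get("label")
        seed = g.attrs.get("seed")
        return Codebook(
            prototypes=g["prototypes"][...],
            label=None if label is None else str(label),
            distortion=float(g.attrs["distortion"]),
            hyperparameters=json.loads(g.attrs["hyperparameters"]),
            seed=None if seed is None else int(seed),
            distortion_curve=g["distortion_curve"][...])


def export_symbolic_text(path, labels: np.ndarray) -> None:
    """Symbolic sequence as TSV: window_id, label."""
    pd.DataFrame({"window_id": np.arange(len(labels)),
                  "label": np.asarray(labels, dtype=int)}
                 ).to_csv(path, sep="\t", index=False)


def read_signals_text(path, fs: float) -> tuple[np.ndarray, float]:
    """Delimited text matrix (rows = ROIs) with fs supplied by the caller."""
    data = pd.read_csv(path, sep=None, engine="python",
                       header=None).to_numpy(dtype=float)
    return data, fs
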