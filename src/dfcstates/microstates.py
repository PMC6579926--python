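"""Vector-quantized connectivity microstates.

The eigenvalue time series of a group of subjects is concatenated along the
window axis and summarized by a small codebook of k prototype spectra
("FC microstates") learned with the neural-gas algorithm: a rank-based
soft-max vector quantizer in which, for every presented sample, each
prototype moves toward the sample with step size eps * exp(-rank / lambda),
rank being the prototype's position in the distance ordering, while the
neighborhood range lambda and learning rate eps decay exponentially over
training.  Subjects are then encoded as symbolic sequences of
nearest-prototype labels, and an unlabeled subject is classified by
rebuilding its eigenvalue series with each candidate group codebook and
choosing the class with the smaller mean squared reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .graphs import EigenTimeSeries

__all__ = [
    "Codebook",
    "SymbolicSequence",
    "ClassificationResult",
    "neural_gas_fit",
    "encode",
    "reconstruction_error",
    "classify_blind",
]


@dataclass
class Codebook:
    """k prototype eigenvalue vectors learned for one group."""

    prototypes: np.ndarray
    label: str | None = None
    distortion: float = np.nan
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None
    distortion_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]


@dataclass
class SymbolicSequence:
    """Window-wise microstate labels in 1..k for one subject."""

    labels: np.ndarray
    k: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not (
                (self.labels >= 1).all() and (self.labels <= self.k).all()):
            raise ValueError("labels must lie in 1..k")

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class ClassificationResult:
    """Reconstruction-error classification of one unlabeled subject."""

    error_per_class: dict
    assigned_label: str
    margin: float


def _distortion(data: np.ndarray, prototypes: np.ndarray) -> float:
    d2 = cdist(data, prototypes, metric="sqeuclidean")
    return float(d2.min(axis=1).mean())


def neural_gas_fit(data_matrix: np.ndarray, k: int, epochs: int = 50,
                   lambda_schedule: tuple[float, float] | None = None,
                   epsilon_schedule: tuple[float, float] = (0.5, 0.005),
                   n_restarts: int = 5, seed: int = 0,
                   label: str | None = None) -> Codebook:
    """Fit a k-prototype neural-gas codebook to data rows.

    `lambda_schedule` and `epsilon_schedule` give the (initial, final)
    neighborhood range and learning rate, both decayed exponentially over
    ``epochs`` full passes; lambda defaults to (k/2, 0.01).  The best of
    `n_restarts` random initializations by final mean squared quantization
    error is returned, deterministically for a given seed.
    """
    data = np.asarray(data_matrix, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D matrix of row samples")
    n_samples, dim = data.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(data, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct data rows")
    lam0, lam_f = lambda_schedule if lambda_schedule is not None \
        else (max(k / 2.0, 1e-3), 0.01)
    eps0, eps_f = epsilon_schedule
    rng = np.random.default_rng(seed)
    t_max = max(epochs * n_samples - 1, 1)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        init_idx = rng.choice(n_samples, size=k, replace=False)
        protos = data[init_idx].copy()
        curve = np.empty(epochs + 1)
        curve[0] = _distortion(data, protos)
        t = 0
        for epoch in range(epochs):
            order = rng.permutation(n_samples)
            for s in order:
                frac = t / t_max
                lam = lam0 * (lam_f / lam0) ** frac
                eps = eps0 * (eps_f / eps0) ** frac
                diff = data[s] - protos
                d2 = np.einsum("ij,ij->i", diff, diff)
                ranks = np.argsort(np.argsort(d2, kind="stable"))
                protos += (eps * np.exp(-ranks / lam))[:, None] * diff
                t += 1
            curve[epoch + 1] = _distortion(data, protos)
        final = curve[-1]
        if best is None or final < best[0]:
            best = (final, protos, curve)
    assert best is not None
    distortion, protos, curve = best
    return Codebook(prototypes=protos, label=label, distortion=distortion,
                    hyperparameters={
                        "k": k, "epochs": epochs,
                        "lambda_schedule": (lam0, lam_f),
                        "epsilon_schedule": (eps0, eps_f),
                        "n_restarts": n_restarts,
                    },
                    seed=seed, distortion_curve=curve)


def _as_columns(eigen_time_series) -> np.ndarray:
    if isinstance(eigen_time_series, EigenTimeSeries):
        return eigen_time_series.values
    return np.asarray(eigen_time_series, dtype=float)


def encode(eigen_time_series, codebook: Codebook,
           subject_id: str | None = None) -> SymbolicSequence:
    """Assign every window (column) to its nearest prototype (Euclidean).

    Exact distance ties resolve to the lowest prototype index.
    """
    x = _as_columns(eigen_time_series)
    if x.shape[0] != codebook.dim:
        raise ValueError(
            f"series dimension {x.shape[0]} != codebook dimension "
            f"{codebook.dim}")
    d2 = cdist(x.T, codebook.prototypes, metric="sqeuclidean")
    labels = d2.argmin(axis=1) + 1  # argmin takes the first = lowest index
    if subject_id is None and isinstance(eigen_time_series, EigenTimeSeries):
        subject_id = eigen_time_series.subject_id
    return SymbolicSequence(labels=labels, k=codebook.k,
                            subject_id=subject_id)


def reconstruction_error(eigen_time_series, codebook: Codebook) -> float:
    """Mean squared error of rebuilding each column as its nearest prototype."""
    x = _as_columns(eigen_time_series)
    labels = encode(x, codebook).labels
    rebuilt = codebook.prototypes[labels - 1].T
    return float(np.mean((x - rebuilt) ** 2))


def classify_blind(eigen_time_series, codebook_a: Codebook,
                   codebook_b: Codebook) -> ClassificationResult:
    """Assign a subject to the group whose codebook rebuilds it best.

    An exact tie in reconstruction error is flagged as "indeterminate".
    """
    label_a = codebook_a.label or "A"
    label_b = codebook_b.label or "B"
    err_a = reconstruction_error(eigen_time_series, codebook_a)
    err_b = reconstruction_error(eigen_time_series, codebook_b)
    if err_a == err_b:
        assigned = "indeterminate"
    else:
        assigned = label_a if err_a < err_b else label_b
    return ClassificationResult(
        error_per_class={label_a: err_a, label_b: err_b},
        assigned_label=assigned, margin=abs(err_a - err_b))
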