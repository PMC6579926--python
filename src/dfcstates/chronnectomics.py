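"""Markov-chain summaries of microstate symbolic sequences.

A subject's window-wise microstate labels form a symbolic time series whose
switching behavior is summarized by: the first-order transition probability
matrix P (row-normalized transition counts, so each visited row sums to 1);
fractional occupancy OT (time share per state); dwell time DT (mean length
of maximal consecutive runs per state); the flexibility index FI (fraction
of consecutive windows with a state change); and the complexity index CI
(distinct-word richness of the sequence over word lengths 1..L, normalized
by the mean richness of label-shuffled surrogates).  Shuffle surrogates also
provide p-values per measure and a significance mask for the transition
digraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionModel",
    "ChronnectomicSummary",
    "transition_matrix",
    "fractional_occupancy",
    "dwell_time",
    "flexibility_index",
    "complexity_index",
    "word_richness",
    "surrogate_pvalue",
    "significant_digraph",
    "summarize_sequence",
]


@dataclass
class TransitionModel:
    """Transition counts and row-stochastic probabilities of a sequence."""

    counts: np.ndarray
    probabilities: np.ndarray
    visited: np.ndarray  # mask: state has at least one outgoing transition


@dataclass
class ChronnectomicSummary:
    """All temporal measures of one symbolic sequence, with p-values."""

    flexibility: float
    occupancy: np.ndarray
    dwell_segments: np.ndarray
    dwell_seconds: np.ndarray
    complexity: float
    transition_model: TransitionModel
    p_values: dict = field(default_factory=dict)
    n_surrogates: int = 0
    seed: int | None = None


def _as_sequence(sequence, k: int) -> np.ndarray:
    seq = np.asarray(sequence, dtype=int)
    if seq.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    if seq.size and ((seq < 1).any() or (seq > k).any()):
        raise ValueError(f"labels must lie in 1..{k}")
    return seq


def transition_matrix(sequence, k: int) -> TransitionModel:
    """First-order transition counts N_ij and row-normalized P_ij.

    Rows without outgoing transitions (unvisited states, or a state seen
    only as the final symbol) are zero and excluded from the visited mask.
    """
    seq = _as_sequence(sequence, k)
    if seq.size < 2:
        raise ValueError("need at least 2 symbols to count transitions")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (seq[:-1] - 1, seq[1:] - 1), 1)
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    probs = np.zeros((k, k))
    probs[visited] = counts[visited] / row_sums[visited, None]
    return TransitionModel(counts=counts, probabilities=probs,
                           visited=visited)


def fractional_occupancy(sequence, k: int) -> np.ndarray:
    """Fraction of windows spent in each state; sums to 1."""
    seq = _as_sequence(sequence, k)
    if seq.size < 1:
        raise ValueError("need at least 1 symbol")
    return np.bincount(seq - 1, minlength=k) / seq.size


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of every maximal consecutive run."""
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate([[-1], change, [seq.size - 1]])
    lengths = np.diff(bounds)
    states = seq[bounds[1:]]
    return states, lengths


def dwell_time(sequence, k: int, step_seconds: float | None = None
               ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Mean maximal-run length per state, in segments (and seconds).

    Unvisited states get dwell time 0.  With `step_seconds` given, returns
    `(segments, seconds)` where seconds = segments * step_seconds.
    """
    seq = _as_sequence(sequence, k)
    if seq.size < 1:
        raise ValueError("need at least 1 symbol")
    states, lengths = _run_lengths(seq)
    dt = np.zeros(k)
    for c in range(1, k + 1):
        mask = states == c
        if mask.any():
            dt[c - 1] = lengths[mask].mean()
    if step_seconds is None:
        return dt
    return dt, dt * step_seconds


def flexibility_index(sequence) -> float:
    """Fraction of consecutive window pairs with a state change."""
    seq = np.asarray(sequence, dtype=int)
    if seq.size < 2:
        raise ValueError("need at least 2 symbols")
    return float(np.mean(seq[1:] != seq[:-1]))


def word_richness(sequence, max_word_length: int) -> int:
    """Total number of distinct words over all lengths 1..max_word_length.

    Words are read from overlapping sliding windows of the sequence.
    """
    seq = np.asarray(sequence, dtype=int)
    if seq.size < max_word_length:
        raise ValueError("sequence shorter than max_word_length")
    total = 0
    for length in range(1, max_word_length + 1):
        view = np.lib.stride_tricks.sliding_window_view(seq, length)
        total += np.unique(view, axis=0).shape[0]
    return int(total)


def complexity_index(sequence, k: int, max_word_length: int = 4,
                     n_surrogates: int = 100, seed: int = 0) -> float:
    """Distinct-word richness normalized by label-shuffled surrogates.

    CI = richness(sequence) / mean richness of `n_surrogates` uniformly
    permuted copies; a sequence richer than chance scores above 1, a
    strongly patterned (e.g. periodic or constant) sequence below or at 1.
    """
    seq = _as_sequence(sequence, k)
    observed = word_richness(seq, max_word_length)
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        null[s] = word_richness(rng.permutation(seq), max_word_length)
    return float(observed / null.mean())


_MEASURES = ("FI", "OT", "DT", "P")


def _measure_value(seq: np.ndarray, k: int, measure: str,
                   state: int | None, ij: tuple[int, int] | None) -> float:
    if measure == "FI":
        return flexibility_index(seq)
    if measure == "OT":
        if state is None:
            raise ValueError("OT requires a state")
        return float(fractional_occupancy(seq, k)[state - 1])
    if measure == "DT":
        if state is None:
            raise ValueError("DT requires a state")
        return float(dwell_time(seq, k)[state - 1])
    if measure == "P":
        if ij is None:
            raise ValueError("P requires an (i, j) transition")
        i, j = ij
        return float(transition_matrix(seq, k).probabilities[i - 1, j - 1])
    raise ValueError(f"unknown measure {measure!r}; expected one of "
                     f"{_MEASURES}")


def surrogate_pvalue(sequence, measure: str, n_surrogates: int = 199,
                     seed: int = 0, direction: str = "greater", *,
                     k: int | None = None, state: int | None = None,
                     ij: tuple[int, int] | None = None) -> float:
    """Shuffle-surrogate p-value of a sequence measure.

    `measure` is one of "FI", "OT", "DT", "P" (the latter three indexed by
    `state` or `ij`, 1-based); surrogates are uniform random permutations of
    the labels and p = (r + 1)/(n_surrogates + 1) with r counting surrogates
    at least as extreme as the observation in `direction`
    ("greater"/"less").  Permutation-invariant measures (occupancy) are
    degenerate under this null and return p = 1 by construction.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    seq = np.asarray(sequence, dtype=int)
    if k is None:
        k = int(seq.max())
    seq = _as_sequence(seq, k)
    observed = _measure_value(seq, k, measure, state, ij)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_surrogates):
        val = _measure_value(rng.permutation(seq), k, measure, state, ij)
        if direction == "greater":
            r += val >= observed
        else:
            r += val <= observed
    return (r + 1) / (n_surrogates + 1)


def significant_digraph(transition_model: TransitionModel, sequence,
                        n_surrogates: int = 199, alpha: float = 0.05,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mask the transition matrix to shuffle-significant entries.

    Every P_ij is compared against the transition probabilities of
    label-shuffled sequences; entries with p < alpha (direction: greater)
    keep their original value, others are zeroed.  Returns
    `(masked_P, p_values)`; no renormalization is applied.
    """
    k = transition_model.probabilities.shape[0]
    seq = _as_sequence(sequence, k)
    observed = transition_model.probabilities
    rng = np.random.default_rng(seed)
    r = np.zeros((k, k), dtype=int)
    for _ in range(n_surrogates):
        perm = transition_matrix(rng.permutation(seq), k).probabilities
        r += perm >= observed
    p = (r + 1) / (n_surrogates + 1)
    masked = np.where(p < alpha, observed, 0.0)
    return masked, p


def summarize_sequence(sequence, k: int, step_seconds: float = 0.05,
                       max_word_length: int = 4, n_surrogates: int = 199,
                       seed: int = 0) -> ChronnectomicSummary:
    """All chronnectomic measures of one sequence plus surrogate p-values."""
    seq = _as_sequence(sequence, k)
    tm = transition_matrix(seq, k)
    dt_seg, dt_sec = dwell_time(seq, k, step_seconds=step_seconds)
    ss = np.random.SeedSequence([seed])
    child = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2 + k)]
    p_values = {
        "FI": surrogate_pvalue(seq, "FI", n_surrogates, child[0], k=k),
        "DT": {c: surrogate_pvalue(seq, "DT", n_surrogates, child[1 + c - 1],
                                   k=k, state=c)
               for c in range(1, k + 1) if tm.visited[c - 1]},
        "OT": {c: surrogate_pvalue(seq, "OT", n_surrogates, child[-1],
                                   k=k, state=c)
               for c in range(1, k + 1)},
    }
    return ChronnectomicSummary(
        flexibility=flexibility_index(seq),
        occupancy=fractional_occupancy(seq, k),
        dwell_segments=dt_seg, dwell_seconds=dt_sec,
        complexity=complexity_index(seq, k, max_word_length,
                                    n_surrogates, seed),
        transition_model=tm, p_values=p_values,
        n_surrogates=n_surrogates, seed=seed)
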