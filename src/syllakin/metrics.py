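"""Behavioral quantities computed from syllable labels and centroid tracks.

All kinematic quantities are in mm and mm/s; entropies default to bits.
Transition matrices are built on the run-length-encoded label sequence
(self-transitions excluded), the standard motion-sequencing convention; both
the log base and the self-transition policy are recorded on the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "run_length_encode",
    "TransitionSummary",
    "centroid_speed_series",
    "syllable_velocity",
    "session_velocity",
    "usage",
    "filter_expressed",
    "transition_matrix",
    "steady_state",
    "entropy",
    "transition_frequency",
    "summarize_transitions",
    "delta_table",
    "group_syllable_stats",
]


def _labels_of(seq) -> np.ndarray:
    labels = getattr(seq, "labels", seq)
    return np.asarray(labels, dtype=np.int64)


def run_length_encode(labels) -> tuple[np.ndarray, np.ndarray]:
    """RLE of a label sequence -> (run values, run lengths in frames)."""
    labels = _labels_of(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


@dataclass
class TransitionSummary:
    """Transition structure of one label sequence over a fixed alphabet.

    ``counts[i, j]`` is the number of run-level transitions syllable
    ``alphabet[i]`` -> ``alphabet[j]``; ``A`` is the row-normalized matrix
    (rows with no outgoing transitions are left as zero rows). ``pi``,
    ``entropy_`` and ``transition_frequency_`` are filled by
    :func:`summarize_transitions`.
    """

    alphabet: np.ndarray
    counts: np.ndarray
    A: np.ndarray
    log_base: float = 2.0
    exclude_self_transitions: bool = True
    pi: np.ndarray | None = None
    entropy_: float | None = None
    transition_frequency_: float | None = None


def centroid_speed_series(centroid_track: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame speed (mm/s) from a (frames, 2) centroid track.

    The last frame repeats the previous speed so the series aligns with the
    per-frame labels.
    """
    c = np.asarray(centroid_track, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(c, axis=0), axis=1) * fps
    return np.concatenate([steps, steps[-1:]])


def syllable_velocity(speeds: np.ndarray, seq) -> dict:
    """Mean speed (mm/s) over the frames assigned to each syllable.

    Syllables absent from the sequence are simply not present in the result
    (missing, not zero).
    """
    speeds = np.asarray(speeds, dtype=float)
    labels = _labels_of(seq)
    if speeds.shape[0] != labels.shape[0]:
        raise ValueError(f"speeds ({speeds.shape[0]}) and labels ({labels.shape[0]}) differ in length")
    out = {}
    for v in np.unique(labels):
        out[int(v)] = float(speeds[labels == v].mean())
    return out


def session_velocity(centroid_track: np.ndarray, fps: float) -> float:
    """Total distance traveled divided by elapsed session time in seconds.

    Elapsed time spans the (T - 1) inter-frame intervals, so constant motion
    of 1 mm/frame at 30 fps gives exactly 30 mm/s.
    """
    c = np.asarray(centroid_track, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    dist = np.linalg.norm(np.diff(c, axis=0), axis=1).sum()
    return float(dist / ((c.shape[0] - 1) / fps))


def usage(seq) -> dict:
    """Fraction of frames spent in each syllable (time basis)."""
    labels = _labels_of(seq)
    vals, counts = np.unique(labels, return_counts=True)
    total = labels.size
    return {int(v): float(c) / total for v, c in zip(vals, counts)}


def filter_expressed(usages: dict, threshold: float = 0.005) -> list:
    """Syllables expressed more than ``threshold`` of the time, sorted."""
    return sorted(k for k, u in usages.items() if u > threshold)


def transition_matrix(seq, alphabet, log_base: float = 2.0,
                      exclude_self_transitions: bool = True) -> TransitionSummary:
    """Run-level transition counts and row-stochastic matrix over ``alphabet``.

    The sequence is run-length encoded first, so only changes between
    distinct syllables count; transitions touching a syllable outside the
    alphabet are dropped. With ``exclude_self_transitions=False`` the raw
    frame-to-frame bigrams (including self-loops) are counted instead.
    """
    alphabet = np.asarray(sorted(alphabet), dtype=np.int64)
    if alphabet.size == 0:
        raise ValueError("alphabet must be non-empty")
    labels = _labels_of(seq)
    if exclude_self_transitions:
        src_labels, _ = run_length_encode(labels)
    else:
        src_labels = labels
    index = {int(v): i for i, v in enumerate(alphabet)}
    K = alphabet.size
    counts = np.zeros((K, K))
    a = src_labels[:-1]
    b = src_labels[1:]
    for x, y in zip(a, b):
        i = index.get(int(x))
        j = index.get(int(y))
        if i is not None and j is not None:
            counts[i, j] += 1.0
    A = np.zeros_like(counts)
    row_sums = counts.sum(axis=1)
    nz = row_sums > 0
    A[nz] = counts[nz] / row_sums[nz, None]
    return TransitionSummary(
        alphabet=alphabet,
        counts=counts,
        A=A,
        log_base=log_base,
        exclude_self_transitions=exclude_self_transitions,
    )


def steady_state(A: np.ndarray, empirical_mass: np.ndarray | None = None,
                 tol: float = 1e-12, max_iter: int = 200000) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by power iteration.

    States with no outgoing transitions are excluded from the support. If the
    chain splits into multiple closed communicating classes, the class
    carrying the most empirical mass (row sums of ``empirical_mass``, else
    uniform) is used and a warning logged; other states get probability 0.
    """
    A = np.asarray(A, dtype=float)
    K = A.shape[0]
    support = A.sum(axis=1) > 0
    pi = np.zeros(K)
    # prune states whose outgoing mass all leaks to unsupported states
    while True:
        if not support.any():
            raise ValueError("matrix has no recurrent transitions")
        idx = np.flatnonzero(support)
        rs = A[np.ix_(idx, idx)].sum(axis=1)
        if (rs > 0).all():
            break
        support[idx[rs == 0]] = False
    sub = A[np.ix_(idx, idx)] / rs[:, None]

    n_comp, comp = connected_components(sub > 0, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = comp == c
        leaves = sub[members][:, ~members].sum()
        if leaves == 0:
            closed.append(c)
    if len(closed) > 1:
        logger.warning("reducible chain with %d closed classes; using the heaviest", len(closed))
        if empirical_mass is None:
            mass = np.ones(len(idx))
        else:
            mass = np.asarray(empirical_mass, dtype=float)[idx]
        best = max(closed, key=lambda c: mass[comp == c].sum())
    else:
        best = closed[0]
    members = np.flatnonzero(comp == best)
    core = sub[np.ix_(members, members)]
    core = core / core.sum(axis=1, keepdims=True)
    p = np.full(len(members), 1.0 / len(members))
    for _ in range(max_iter):
        p_next = p @ core
        # damp period-2 oscillations (e.g., cyclic chains)
        p_next = 0.5 * (p_next + p_next @ core)
        if np.abs(p_next - p).max() < tol:
            p = p_next
            break
        p = p_next
    p = p / p.sum()
    pi[idx[members]] = p
    return pi


def entropy(summary: TransitionSummary, log_base: float | None = None, mode: str = "rate") -> float:
    """Entropy of the transition structure, in units of ``log_base``.

    ``mode="rate"``: ``-sum_ij pi_i A_ij log A_ij`` (steady-state weighted).
    ``mode="local_sum"``: unweighted sum of per-row entropies. Both are
    returned positive; zero rows contribute nothing.
    """
    if mode not in ("rate", "local_sum"):
        raise ValueError(f"invalid entropy mode {mode!r}")
    base = float(log_base if log_base is not None else summary.log_base)
    A = summary.A
    support = A.sum(axis=1) > 0
    logA = np.zeros_like(A)
    np.log(A, out=logA, where=A > 0)
    row_h = -(A * logA).sum(axis=1) / np.log(base)
    if mode == "local_sum":
        return float(row_h[support].sum())
    pi = summary.pi if summary.pi is not None else steady_state(A, summary.counts.sum(axis=1))
    return float((pi[support] * row_h[support]).sum())


def transition_frequency(seq, fps: float | None = None) -> float:
    """Syllable label changes per second of recording."""
    labels = _labels_of(seq)
    if fps is None:
        fps = seq.fps
    changes = int((np.diff(labels) != 0).sum())
    return changes / (labels.size / fps)


def summarize_transitions(seq, alphabet, fps: float | None = None, log_base: float = 2.0,
                          exclude_self_transitions: bool = True,
                          entropy_mode: str = "rate") -> TransitionSummary:
    """One-stop transition summary: counts, A, steady state, entropy, frequency."""
    summary = transition_matrix(seq, alphabet, log_base=log_base,
                                exclude_self_transitions=exclude_self_transitions)
    summary.pi = steady_state(summary.A, summary.counts.sum(axis=1))
    summary.entropy_ = entropy(summary, mode=entropy_mode)
    summary.transition_frequency_ = transition_frequency(seq, fps)
    return summary


def delta_table(stats_control: pd.DataFrame, stats_other: pd.DataFrame) -> pd.DataFrame:
    """Per-syllable control-minus-other differences joined with control velocity.

    Both inputs are indexed by syllable with ``velocity`` and ``usage``
    columns (e.g., from :func:`group_syllable_stats`). Unmatched syllables
    are dropped with a log line.
    """
    common = stats_control.index.intersection(stats_other.index)
    if common.empty:
        raise ValueError("no shared syllables between the two groups")
    dropped = stats_control.index.symmetric_difference(stats_other.index)
    if len(dropped):
        logger.info("delta_table: dropping unmatched syllables %s", list(dropped))
    a = stats_control.loc[common]
    b = stats_other.loc[common]
    return pd.DataFrame({
        "control_velocity": a["velocity"],
        "delta_velocity": a["velocity"] - b["velocity"],
        "delta_usage": a["usage"] - b["usage"],
    }, index=common)


def group_syllable_stats(per_animal: list) -> pd.DataFrame:
    """Aggregate per-animal syllable metrics into group mean +/- sem.

    ``per_animal`` is a list of dicts with keys ``velocity`` and ``usage``,
    each mapping syllable -> value (as returned by :func:`syllable_velocity`
    and :func:`usage`). Animals missing a syllable contribute no velocity
    estimate for it (usage contributes 0). Returns a DataFrame indexed by
    syllable with velocity/usage means, sems and per-syllable n.
    """
    if not per_animal:
        raise ValueError("no animals")
    syllables = sorted({s for d in per_animal for s in d["velocity"]})
    rows = []
    for s in syllables:
        vels = np.array([d["velocity"][s] for d in per_animal if s in d["velocity"]])
        uses = np.array([d["usage"].get(s, 0.0) for d in per_animal])
        rows.append({
            "syllable": s,
            "velocity": vels.mean(),
            "velocity_sem": vels.std(ddof=1) / np.sqrt(len(vels)) if len(vels) > 1 else 0.0,
            "usage": uses.mean(),
            "usage_sem": uses.std(ddof=1) / np.sqrt(len(uses)) if len(uses) > 1 else 0.0,
            "n_velocity": len(vels),
        })
    return pd.DataFrame(rows).set_index("syllable")
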