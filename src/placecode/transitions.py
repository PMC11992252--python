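"""Functional-class transition statistics against a shuffled-class null.

Tracked neurons carry a functional class (stable place cell, unstable place
cell, non-coding) per session or phase. The observed transition probability
P(a→b) between two time points is compared to a chance level obtained by
permuting the second time point's labels across cells; ΔP = P_true −
P_shuffle is positive when a transition happens more often than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TransitionStats", "transition_probabilities", "shuffled_delta_p"]

DEFAULT_CLASSES = ("stable_pc", "unstable_pc", "noncoding")


@dataclass
class TransitionStats:
    """Observed, chance and excess transition probabilities.

    All matrices are from-class × to-class DataFrames; rows of ``p_true`` sum
    to 1 over to-classes (NaN row when the from-class is empty at t1).
    """

    p_true: pd.DataFrame
    p_shuffle: pd.DataFrame
    delta_p: pd.DataFrame
    shuffle_sd: pd.DataFrame
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: from_class, to_class, P_true, P_shuffle, delta_P, shuffle_sd, n."""
        rows = []
        for a in self.p_true.index:
            for b in self.p_true.columns:
                rows.append({
                    "from_class": a, "to_class": b,
                    "P_true": self.p_true.loc[a, b],
                    "P_shuffle": self.p_shuffle.loc[a, b],
                    "delta_P": self.delta_p.loc[a, b],
                    "shuffle_sd": self.shuffle_sd.loc[a, b],
                    "n": self.n_cells,
                })
        return pd.DataFrame(rows)


def _transition_matrix(labels_t1, labels_t2, classes) -> np.ndarray:
    t1 = np.asarray(labels_t1)
    t2 = np.asarray(labels_t2)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k))
    for a, b in zip(t1, t2):
        counts[idx[a], idx[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
    p[totals[:, 0] == 0] = np.nan
    return p


def transition_probabilities(labels_t1, labels_t2,
                             classes=DEFAULT_CLASSES) -> pd.DataFrame:
    """Observed P(a→b) over the same tracked cells at two time points."""
    t1, t2 = np.asarray(labels_t1), np.asarray(labels_t2)
    if t1.shape != t2.shape:
        raise ValueError("label vectors must cover the same tracked cells")
    p = _transition_matrix(t1, t2, classes)
    return pd.DataFrame(p, index=list(classes), columns=list(classes))


def shuffled_delta_p(labels_t1, labels_t2, n_shuffles: int = 1000, seed=None,
                     classes=DEFAULT_CLASSES) -> TransitionStats:
    """Excess transition probability over a label-permutation null.

    Per shuffle the t2 labels are permuted across cells (equivalent to
    permuting t1 for this statistic) and the transition matrix recomputed;
    ΔP = P_true − mean(P_shuffle) per entry, with the shuffle SD retained
    for z-scoring. Row sums of ΔP are 0 by construction wherever defined.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a usable null")
    t1, t2 = np.asarray(labels_t1), np.asarray(labels_t2)
    if t1.shape != t2.shape:
        raise ValueError("label vectors must cover the same tracked cells")
    rng = np.random.default_rng(seed)
    p_true = _transition_matrix(t1, t2, classes)
    draws = np.empty((n_shuffles,) + p_true.shape)
    for s in range(n_shuffles):
        draws[s] = _transition_matrix(t1, rng.permutation(t2), classes)
    p_shuf = draws.mean(axis=0)
    sd = draws.std(axis=0)
    as_df = lambda m: pd.DataFrame(m, index=list(classes), columns=list(classes))
    return TransitionStats(
        p_true=as_df(p_true), p_shuffle=as_df(p_shuf),
        delta_p=as_df(p_true - p_shuf), shuffle_sd=as_df(sd),
        n_cells=len(t1),
    )
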