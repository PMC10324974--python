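"""Redundancy-relevance feature filter.

Redundant feature pairs are found with Kendall's tau (the tie-uncorrected
tau-a: the average of sign-concordance over all sample pairs); of any pair
correlated above the threshold, the member carrying less mutual information
with the response (reference power) is dropped.  Relevance uses the discrete
mutual information of equal-frequency-binned variables, in bits.

Selection is performed on the development set only; the test set inherits
the selected columns unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "SelectionReport",
    "kendall_tau",
    "mutual_information",
    "select_features",
]


def kendall_tau(x, y) -> float:
    """Kendall's tau-a: 2/(N(N-1)) * sum_{i<j} sgn(xi-xj) sgn(yi-yj).

    Computed in O(N log N) from scipy's tau-b by undoing the tie
    normalization; a variable with all values tied yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    n0 = n * (n - 1) / 2.0

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float((counts * (counts - 1) / 2.0).sum())

    n1, n2 = tie_term(x), tie_term(y)
    if n0 == n1 or n0 == n2:  # a constant vector: every pair tied
        return 0.0
    tau_b = sstats.kendalltau(x, y).statistic
    c_minus_d = tau_b * np.sqrt((n0 - n1) * (n0 - n2))
    return float(c_minus_d / n0)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Bin labels from equal-frequency (quantile) edges; rank-stable."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(x, y, bins: int = 10) -> float:
    """Discrete mutual information I(X;Y) in bits.

    Both variables are discretized into ``bins`` equal-frequency bins; the
    plug-in estimate sums p(x,y) log2 p(x,y)/(p(x)p(y)) over the joint
    histogram with the 0 log 0 = 0 convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    joint = np.zeros((bx.max() + 1, by.max() + 1))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


@dataclass
class SelectionReport:
    """Outcome of the redundancy-relevance filter."""

    kept: list
    dropped: dict  # name -> reason ("redundant-lower-MI vs <other>")
    tau_pairs: dict  # (name_a, name_b) -> tau for pairs above threshold
    mi: dict  # feature name -> I(feature; response), bits
    tau_threshold: float = 0.8

    def __post_init__(self):
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValueError(f"features both kept and dropped: {sorted(overlap)}")

    def to_json(self, path=None) -> str:
        payload = {
            "kept": self.kept,
            "dropped": self.dropped,
            "tau_threshold": self.tau_threshold,
            "mi": self.mi,
            "tau_pairs": {f"{a}|{b}": t for (a, b), t in self.tau_pairs.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_features(Xd: pd.DataFrame, Pd, tau_threshold: float = 0.8,
                    bins: int = 10) -> SelectionReport:
    """Drop the less response-informative member of every redundant pair.

    All feature pairs with |tau| >= ``tau_threshold`` are processed in
    descending |tau| order (ties broken by name); at each step the member
    with the lower mutual information with the response is dropped (MI ties
    broken by keeping the lexicographically earlier name). Pairs whose
    member was already dropped are skipped.
    """
    if Xd.shape[1] == 0 or Xd.shape[0] == 0:
        raise ValueError("empty feature table")
    Pd = np.asarray(Pd, dtype=float)
    names = list(Xd.columns)
    cols = {c: Xd[c].to_numpy(float) for c in names}
    mi = {c: mutual_information(cols[c], Pd, bins=bins) for c in names}

    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t = kendall_tau(cols[a], cols[b])
            if abs(t) >= tau_threshold:
                pairs.append((a, b, t))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))

    dropped: dict = {}
    for a, b, t in pairs:
        if a in dropped or b in dropped:
            continue
        if mi[a] > mi[b]:
            loser, winner = b, a
        elif mi[b] > mi[a]:
            loser, winner = a, b
        else:  # MI tie: keep the lexicographically earlier name
            winner, loser = sorted((a, b))
        dropped[loser] = f"redundant-lower-MI vs {winner} (|tau|={abs(t):.3f})"
    kept = [c for c in names if c not in dropped]
    return SelectionReport(kept=kept, dropped=dropped,
                           tau_pairs={(a, b): t for a, b, t in pairs},
                           mi=mi, tau_threshold=tau_threshold)
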