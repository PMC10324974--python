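"""Agreement between predicted and reference power.

Predicted and reference per-second series are smoothed with a 10-s sliding
window advancing 5 s (one estimate every 5 s), compared through the signed
percentage error

    eps = (Pt - Pt_hat) / Pt * 100,

and summarized as bias (median of eps), precision (IQR of eps), mean
absolute error, squared correlations, Bland-Altman limits of agreement and
the cumulative distribution of |eps|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "smooth",
    "percent_error",
    "summarize",
    "AgreementReport",
    "plot_agreement",
    "plot_bland_altman",
    "plot_error_cdf",
]


def smooth(values, window: int = 10, overlap: int = 5) -> np.ndarray:
    """Sliding-window means: a ``window``-s mean every ``window - overlap`` s.

    A 60-s series yields 11 outputs 5 s apart with the defaults. Series
    shorter than one window produce an empty output with a warning.
    """
    x = np.asarray(values, dtype=float)
    hop = window - overlap
    if hop <= 0:
        raise ValueError("overlap must be smaller than the window")
    if x.size < window:
        warnings.warn(f"series of {x.size} s shorter than the {window}-s window")
        return np.empty(0)
    starts = np.arange(0, x.size - window + 1, hop)
    return np.array([x[s:s + window].mean() for s in starts])


def percent_error(pt, pt_hat) -> np.ndarray:
    """Signed percentage error of the estimate w.r.t. the reference.

    Samples with zero reference power are excluded (count logged via a
    warning); the sign convention follows the reference, so an
    underestimated magnitude gives a positive error on negative (downhill)
    powers too.
    """
    pt = np.asarray(pt, dtype=float)
    pt_hat = np.asarray(pt_hat, dtype=float)
    if pt.shape != pt_hat.shape:
        raise ValueError("reference and estimate must have equal length")
    ok = pt != 0.0
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} sample(s) with zero reference power")
    return (pt[ok] - pt_hat[ok]) / pt[ok] * 100.0


@dataclass
class AgreementReport:
    """Agreement metrics between reference and estimated power."""

    bias: float  # median of eps, %
    precision: float  # IQR of eps, %
    mae: float  # mean |eps|, %
    r2: float  # squared Pearson correlation of the smoothed series
    r2_kendall: float  # squared Kendall tau (rank agreement)
    n: int
    bland_altman_mean_diff: float  # W
    bland_altman_loa: tuple  # (low, high), mean diff +- 1.96 SD, W
    errors: np.ndarray = field(repr=False)
    by_condition: pd.DataFrame | None = field(default=None, repr=False)

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted |eps| with cumulative fraction."""
        a = np.sort(np.abs(self.errors))
        return a, np.arange(1, a.size + 1) / a.size

    def to_dict(self) -> dict:
        return {"bias": self.bias, "precision": self.precision, "mae": self.mae,
                "r2": self.r2, "r2_kendall": self.r2_kendall, "n": self.n,
                "bland_altman_mean_diff": self.bland_altman_mean_diff,
                "bland_altman_loa": list(self.bland_altman_loa)}

    def summary(self) -> str:
        lines = [
            "Power estimation agreement",
            "=" * 40,
            f"samples (5-s estimates):  {self.n}",
            f"bias (median eps):        {self.bias:+.1f} %",
            f"precision (IQR eps):      {self.precision:.1f} %",
            f"MAE:                      {self.mae:.1f} %",
            f"R^2 (Pearson):            {self.r2:.3f}",
            f"R^2 (Kendall):            {self.r2_kendall:.3f}",
            f"Bland-Altman mean diff:   {self.bland_altman_mean_diff:+.1f} W",
            f"limits of agreement:      [{self.bland_altman_loa[0]:+.1f}, "
            f"{self.bland_altman_loa[1]:+.1f}] W",
        ]
        return "\n".join(lines)


def summarize(errors, pt=None, pt_hat=None, conditions=None) -> AgreementReport:
    """Summarize a percentage-error series (optionally with power pairs).

    ``pt``/``pt_hat`` are the aligned smoothed series used for the
    correlation and Bland-Altman statistics; ``conditions`` is an optional
    per-sample (speed, grade) label frame for the condition breakdown.
    IQR uses linearly interpolated quantiles.
    """
    eps = np.asarray(errors, dtype=float)
    if eps.size == 0:
        raise ValueError("empty error series")
    q75, q25 = np.percentile(eps, [75, 25])
    bias = float(np.median(eps))
    precision = float(q75 - q25)
    mae = float(np.mean(np.abs(eps)))
    r2 = r2k = np.nan
    ba_mean, loa = np.nan, (np.nan, np.nan)
    if pt is not None and pt_hat is not None:
        pt = np.asarray(pt, dtype=float)
        pt_hat = np.asarray(pt_hat, dtype=float)
        if pt.size >= 2 and np.std(pt) > 0 and np.std(pt_hat) > 0:
            r2 = float(np.corrcoef(pt, pt_hat)[0, 1] ** 2)
            r2k = float(sstats.kendalltau(pt, pt_hat).statistic ** 2)
        diff = pt - pt_hat
        ba_mean = float(diff.mean())
        sd = float(diff.std(ddof=0))
        loa = (ba_mean - 1.96 * sd, ba_mean + 1.96 * sd)
    by_cond = None
    if conditions is not None:
        frame = pd.DataFrame(conditions).copy()
        frame["eps"] = eps
        by_cond = (frame.groupby(list(frame.columns[:-1]))["eps"]
                   .agg(bias="median",
                        precision=lambda e: float(np.subtract(*np.percentile(e, [75, 25]))),
                        mae=lambda e: float(np.mean(np.abs(e))), n="count")
                   .reset_index())
    return AgreementReport(bias=bias, precision=precision, mae=mae, r2=r2,
                           r2_kendall=r2k, n=eps.size,
                           bland_altman_mean_diff=ba_mean, bland_altman_loa=loa,
                           errors=eps, by_condition=by_cond)


# ---------------------------------------------------------------------------
# Plots (matplotlib figures; callers decide on saving/showing)


def plot_agreement(pt, pt_hat, ax=None):
    """Reference-vs-estimate scatter with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pt, pt_hat, s=8, alpha=0.6)
    lim = [min(np.min(pt), np.min(pt_hat)), max(np.max(pt), np.max(pt_hat))]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("reference power (W)")
    ax.set_ylabel("estimated power (W)")
    return ax


def plot_bland_altman(pt, pt_hat, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pt = np.asarray(pt, dtype=float)
    pt_hat = np.asarray(pt_hat, dtype=float)
    mean = (pt + pt_hat) / 2.0
    diff = pt - pt_hat
    md, sd = diff.mean(), diff.std(ddof=0)
    ax.scatter(mean, diff, s=8, alpha=0.6)
    for y, style in ((md, "-"), (md + 1.96 * sd, "--"), (md - 1.96 * sd, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of reference and estimate (W)")
    ax.set_ylabel("reference - estimate (W)")
    return ax


def plot_error_cdf(report: AgreementReport, ax=None, label=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a, frac = report.cdf()
    ax.step(a, frac, where="post", label=label)
    ax.set_xlabel("|error| (%)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1)
    return ax
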