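"""Bland–Altman method agreement for paired BV/TV measurements.

Two methods measuring the same quantity on the same samples are compared on
their paired differences: the bias is the mean difference, the 95% limits
of agreement are mean ± 1.96 SD (classical Bland–Altman, sample SD), and a
two-sided one-sample t test asks whether the bias differs from zero.
Normality of the differences is checked with Shapiro–Wilk.  The difference
orientation is fixed and reported as ``a − b`` (conventionally reference
method minus new method, e.g. CT − MRI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "bland_altman",
    "shapiro_wilk",
    "bland_altman_plot",
]


@dataclass
class PairedMeasurements:
    """Paired per-sample values from two methods (a = reference, b = new)."""

    sample_ids: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if not (len(self.sample_ids) == self.a.size == self.b.size):
            raise ValueError("sample_ids, a and b must have equal lengths")
        if self.a.size < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("measurements must be finite")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, a_col: str = "ct_bvtv", b_col: str = "mri_bvtv",
        id_col: str = "sample_id",
    ) -> "PairedMeasurements":
        return cls(df[id_col].astype(str).tolist(), df[a_col].to_numpy(), df[b_col].to_numpy())


@dataclass
class AgreementResult:
    """Bland–Altman summary of paired differences d = a − b.

    ``degenerate_t`` flags a zero-variance difference vector, for which the
    t statistic is undefined.
    """

    n: int
    orientation: str
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    shapiro_w: float
    shapiro_p: float
    t_stat: float
    t_df: int
    t_p: float
    degenerate_t: bool = False
    table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "orientation": self.orientation,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
            "t_stat": self.t_stat,
            "t_df": self.t_df,
            "t_p": self.t_p,
            "degenerate_t": self.degenerate_t,
        }


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p), 3 ≤ n ≤ 5000."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland–Altman analysis of ``pairs`` with a one-sample t test on d = a − b.

    The per-sample table of (mean of pair, difference) needed for the
    classical plot is attached as ``table``.
    """
    d = pairs.a - pairs.b
    n = d.size
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    if n >= 3 and np.ptp(d) > 0:
        shapiro_w, shapiro_p = shapiro_wilk(d)
    else:
        shapiro_w, shapiro_p = float("nan"), float("nan")
    degenerate = sd_diff == 0
    if degenerate:
        t_stat, t_p = float("nan"), float("nan")
    else:
        res = stats.ttest_1samp(d, 0.0, alternative="two-sided")
        t_stat, t_p = float(res.statistic), float(res.pvalue)
    table = pd.DataFrame(
        {
            "sample_id": pairs.sample_ids,
            "a": pairs.a,
            "b": pairs.b,
            "mean": (pairs.a + pairs.b) / 2.0,
            "diff": d,
        }
    )
    return AgreementResult(
        n=n,
        orientation="a - b",
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        shapiro_w=shapiro_w,
        shapiro_p=shapiro_p,
        t_stat=t_stat,
        t_df=n - 1,
        t_p=t_p,
        degenerate_t=degenerate,
        table=table,
    )


def bland_altman_plot(result: AgreementResult, path=None, ax=None):
    """Mean-vs-difference plot with bias and 95% limits of agreement."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = result.table
    ax.scatter(t["mean"], t["diff"], color="k", zorder=3)
    ax.axhline(result.mean_diff, color="tab:blue", label=f"bias {result.mean_diff:.3f}")
    for y, name in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="tab:red", linestyle="--", label=f"{name} {y:.3f}")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel(f"difference ({result.orientation})")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
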