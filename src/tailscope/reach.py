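"""Maximum tail reach: per-frame statistic, quartile summary, Welch comparison.

The reach of one frame is the largest distance between the anchor α-carbon
(P43 for the full H3 tail) and any α-carbon strictly N-terminal of it.  The
quartiles of the per-frame reach distribution later become the inner/outer
radii of the chromatin reach shells, so the quantile convention (linear
interpolation between order statistics) is fixed here once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SelectionError
from .structio import Structure, Trajectory

__all__ = [
    "ReachSeries",
    "ReachSummary",
    "WelchResult",
    "max_reach_frame",
    "reach_series",
    "summarize_reach",
    "welch_test",
]


@dataclass
class ReachSeries:
    """Per-frame maximum reach in Å, anchored at ``anchor_res``."""

    values: np.ndarray
    anchor_res: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("reach values must be nonnegative")

    def to_frame(self, dt: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self.values)), "reach_A": self.values})
        if dt is not None:
            df.insert(1, "time_ps", df["frame"] * dt)
        return df


@dataclass(frozen=True)
class ReachSummary:
    """Five-number box summary of a reach distribution (Å)."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def _anchor_and_nterm(topology: Structure, anchor_res: int):
    ca = [(a.res_seq, i) for i, a in enumerate(topology.atoms) if a.name == "CA"]
    anchor = [i for r, i in ca if r == anchor_res]
    if not anchor:
        raise SelectionError(f"anchor residue {anchor_res} has no Cα")
    nterm = [i for r, i in ca if r < anchor_res]
    if not nterm:
        raise SelectionError(f"no Cα atoms N-terminal of residue {anchor_res}")
    return anchor[0], nterm


def max_reach_frame(frame: np.ndarray, topology: Structure, anchor_res: int) -> float:
    """Maximum |Cα_i − Cα_anchor| over residues i strictly N-terminal of the anchor."""
    frame = np.asarray(frame, dtype=float)
    anchor_idx, nterm_idx = _anchor_and_nterm(topology, anchor_res)
    d = np.linalg.norm(frame[nterm_idx] - frame[anchor_idx], axis=1)
    return float(d.max())


def reach_series(traj: Trajectory, anchor_res: int = 43) -> ReachSeries:
    anchor_idx, nterm_idx = _anchor_and_nterm(traj.topology, anchor_res)
    d = np.linalg.norm(
        traj.frames[:, nterm_idx, :] - traj.frames[:, [anchor_idx], :], axis=2
    )
    return ReachSeries(values=d.max(axis=1), anchor_res=anchor_res)


def summarize_reach(r: ReachSeries, whiskers: str = "iqr") -> ReachSummary:
    """Box summary with linear-interpolation quartiles.

    ``whiskers='iqr'`` uses the Tukey convention (farthest points within
    1.5·IQR of the box); ``whiskers='minmax'`` uses the extremes, in which
    case there are no outliers by construction.
    """
    v = r.values
    if v.size == 0:
        raise ValueError("empty reach series")
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75], method="linear"))
    if whiskers == "minmax":
        lo, hi = float(v.min()), float(v.max())
        n_out = 0
    elif whiskers == "iqr":
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        lo, hi = float(inside.min()), float(inside.max())
        n_out = int(v.size - inside.size)
    else:
        raise ValueError(f"unknown whisker convention '{whiskers}'")
    return ReachSummary(q1, med, q3, lo, hi, n_out)


@dataclass(frozen=True)
class WelchResult:
    """Unpaired two-sided t-test with Welch's unequal-variance correction."""

    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


def welch_test(a: ReachSeries | np.ndarray, b: ReachSeries | np.ndarray) -> WelchResult:
    """Welch t-test of mean reach difference (a minus b), 95% CI."""
    x = a.values if isinstance(a, ReachSeries) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, ReachSeries) else np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        # degenerate: no sampling noise at all
        if np.isclose(x.mean(), y.mean()):
            d = float(x.mean() - y.mean())
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0, d, d, d)
        raise ValueError("both variances zero with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_diff=float(x.mean() - y.mean()),
    )
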