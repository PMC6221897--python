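"""Trial partitioning and the statistical battery.

Tercile partition by reaction time (fast / middle / slow, extreme groups of
floor(n/3) trials) and by chronological order (early / middle / late);
Wilcoxon rank-sum with tie-corrected normal approximation and continuity
correction; per-channel Welch two-sample t; Pearson correlation with
single-trial RT; Bonferroni threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)


@dataclass
class StatsResult:
    """One test's outcome: statistic (z, t or r), df where defined, p."""

    test_name: str
    statistic: float
    p_value: float
    sidedness: str = "two"
    df: float | None = None
    corrected_threshold: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        thr = self.corrected_threshold if self.corrected_threshold is not None else alpha
        return self.p_value < thr


@dataclass
class PartitionLabels:
    """Per-trial class labels.

    ``performance_class`` splits by RT (fast / middle / slow) and
    ``order_class`` by chronological position (early / middle / late); the
    extreme groups each hold floor(n/3) trials. RT ties straddling a group
    boundary are resolved chronologically (the earlier trial takes the
    lower-rank class), which is logged.
    """

    performance_class: np.ndarray
    order_class: np.ndarray

    def mask(self, cls: str) -> np.ndarray:
        if cls in ("fast", "middle", "slow"):
            return self.performance_class == cls
        return self.order_class == cls


def partition_terciles(rts: np.ndarray) -> PartitionLabels:
    """Label each trial fast/middle/slow by RT and early/middle/late by order."""
    rts = np.asarray(rts, dtype=float)
    n = rts.shape[0]
    if n < 6:
        raise ValueError("tercile partition requires at least 6 trials")
    k = n // 3
    chron = np.arange(n)
    order = np.lexsort((chron, rts))  # RT ascending, chronological tie-break
    if np.unique(rts).size < n:
        logger.info("RT ties present; resolved by chronological order")
    perf = np.full(n, "middle", dtype=object)
    perf[order[:k]] = "fast"
    perf[order[n - k :]] = "slow"
    oc = np.full(n, "middle", dtype=object)
    oc[:k] = "early"
    oc[n - k :] = "late"
    return PartitionLabels(performance_class=perf.astype(str), order_class=oc.astype(str))


def rank_sum(x, y, sided: str = "two") -> StatsResult:
    """Wilcoxon rank-sum test of x vs y (normal approximation).

    Uses midranks with tie-corrected variance and a 0.5 continuity
    correction. ``sided`` is ``"two"``, ``"less"`` (x tends smaller) or
    ``"greater"``; the z statistic is positive when x ranks above y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 3 or n2 < 3:
        raise ValueError("each sample needs at least 3 observations")
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        logger.warning("all values tied; rank-sum z undefined, returning 0")
        return StatsResult("rank_sum", 0.0, 1.0, sided)
    d = u1 - mu
    cc = 0.5 if d != 0 else 0.0
    z = (d - np.sign(d) * cc) / np.sqrt(var)
    if sided == "two":
        p = 2 * sstats.norm.sf(abs(z))
    elif sided == "greater":
        p = sstats.norm.sf(z)
    elif sided == "less":
        p = sstats.norm.cdf(z)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return StatsResult("rank_sum", float(z), float(min(p, 1.0)), sided)


@dataclass
class NodalContrast:
    """Per-channel Welch contrast table and its extreme channel."""

    table: pd.DataFrame  # columns: channel, t, df, p
    max_channel: int     # index of max |t|

    def result(self, channel: int) -> StatsResult:
        row = self.table.iloc[channel]
        return StatsResult("welch_t", float(row["t"]), float(row["p"]), "two", df=float(row["df"]))


def nodal_contrast_t(features: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
                     channel_labels=None) -> NodalContrast:
    """Welch two-sample t per channel between two trial groups.

    Parameters
    ----------
    features : (trial, channel) array
    group_a, group_b : boolean masks or index arrays over trials
        e.g. fast vs slow, or early vs late.
    """
    a = features[group_a]
    b = features[group_b]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 trials")
    res = sstats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.atleast_1d(res.statistic).astype(float)
    p = np.atleast_1d(res.pvalue).astype(float)
    df = np.atleast_1d(res.df).astype(float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning("zero variance in both groups for %d channel(s); p set to 1", int(degenerate.sum()))
        t[degenerate], p[degenerate], df[degenerate] = 0.0, 1.0, np.nan
    labels = channel_labels if channel_labels is not None else list(range(t.size))
    table = pd.DataFrame({"channel": labels, "t": t, "df": df, "p": p})
    return NodalContrast(table=table, max_channel=int(np.argmax(np.abs(t))))


def correlate_rt(feature: np.ndarray, rts: np.ndarray) -> StatsResult:
    """Pearson correlation of a per-trial feature with reaction time."""
    feature = np.asarray(feature, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if feature.size < 4:
        raise ValueError("correlation requires at least 4 trials")
    if np.std(feature) == 0 or np.std(rts) == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = sstats.pearsonr(feature, rts)
    return StatsResult("pearson_r", float(r), float(p), "two", df=float(feature.size - 2))


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
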