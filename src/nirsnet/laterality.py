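"""Laterality index over homotopic channel pairs.

The laterality index quantifies hemispheric dominance of activation:

    LI = f * (RHi - LHi) / (|RHi| + |LHi|)

where RHi and LHi are the mean HbO of a right-hemisphere channel and its
homotopic left partner over the first 20 s of the task, and f is an
adjustment factor (1 by default). LI is +1 for exclusively right-sided
activation, -1 for exclusively left-sided, and near 0 when both sides are
similarly active. A pair counts as lateralized at the group level when a
one-sample t-test finds the subjects' LI significantly greater than the
conventional threshold LI_TH = 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BlockAverage
from .montage import Montage

__all__ = [
    "LIConfig",
    "roi_task_mean",
    "compute_li",
    "subject_li_table",
    "group_li_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LIConfig:
    """Laterality-index parameters.

    ``f``: adjustment factor (unitless, 1 by default; must be nonzero).
    ``li_threshold``: group-level lateralization threshold (0.2).
    ``window``: post-onset averaging window, s.
    ``alternative``: sidedness of the group test; "greater" screens for LI
    significantly above the threshold.
    """

    f: float = 1.0
    li_threshold: float = 0.2
    window: tuple[float, float] = (0.0, 20.0)
    alternative: str = "greater"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.f == 0:
            raise ValueError("adjustment factor f must be nonzero")
        if not (0 < self.li_threshold < 1):
            raise ValueError("li_threshold must lie in (0, 1)")


def roi_task_mean(
    avg: BlockAverage, channel: str, window: tuple[float, float] = (0.0, 20.0)
) -> float:
    """Mean block-average HbO of one channel over a post-onset window (s)."""
    times = avg.times
    if window[0] < times[0] or window[1] > times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside the epoch span [{times[0]}, {times[-1]}] s"
        )
    mask = (times >= window[0]) & (times <= window[1])
    return float(avg.data[avg.channel_index(channel), mask].mean())


def compute_li(rhi: float, lhi: float, config: LIConfig = LIConfig()) -> float:
    """Laterality index LI = f * (RHi - LHi) / (|RHi| + |LHi|).

    The degenerate all-zero input (no activation on either side) is mapped
    to 0 — no asymmetry — with a logged warning.
    """
    denom = abs(rhi) + abs(lhi)
    if denom == 0:
        logger.warning("RHi = LHi = 0: laterality undefined, returning 0")
        return 0.0
    return config.f * (rhi - lhi) / denom


def subject_li_table(
    subject_averages: dict[int, BlockAverage],
    montage: Montage,
    config: LIConfig = LIConfig(),
) -> pd.DataFrame:
    """Per-subject LI for each homotopic pair, from condition block averages.

    ``subject_averages`` maps subject id -> that subject's block average for
    one condition. Rows: pair (``"left~right"``), subject, RHi, LHi, li.
    """
    rows = []
    for subject, avg in subject_averages.items():
        for left, right in montage.homotopic_pairs:
            rhi = roi_task_mean(avg, right, config.window)
            lhi = roi_task_mean(avg, left, config.window)
            rows.append(
                (f"{left}~{right}", subject, rhi, lhi, compute_li(rhi, lhi, config))
            )
    return pd.DataFrame(rows, columns=["pair", "subject", "rhi", "lhi", "li"])


def _one_sample_t(
    values: np.ndarray, popmean: float, alternative: str
) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    scale = max(1.0, float(np.abs(values).max()))
    if values.std(ddof=1) <= 1e-12 * scale:  # constant up to rounding
        if np.isclose(values.mean(), popmean, rtol=1e-9, atol=1e-12):
            return 0.0, 1.0  # degenerate: exactly at threshold, not significant
        t = np.inf if values.mean() > popmean else -np.inf
        if alternative == "greater":
            return t, 0.0 if t > 0 else 1.0
        if alternative == "less":
            return t, 0.0 if t < 0 else 1.0
        return t, 0.0
    res = stats.ttest_1samp(values, popmean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def group_li_test(
    li_table: pd.DataFrame, config: LIConfig = LIConfig()
) -> pd.DataFrame:
    """Group-level lateralization test per homotopic pair.

    One-sample t of the subjects' LI against ``li_threshold`` (one-sided
    "greater" by default); a pair is flagged lateralized when p < alpha.
    Returns one row per pair: n, mean_li, t, p, lateralized, sig marks.
    """
    rows = []
    for pair, grp in li_table.groupby("pair", sort=False):
        values = grp["li"].to_numpy()
        t, p = _one_sample_t(values, config.li_threshold, config.alternative)
        rows.append(
            {
                "pair": pair,
                "n": values.size,
                "mean_li": float(values.mean()),
                "t": t,
                "p": p,
                "lateralized": bool(p < config.alpha),
                "sig_05": bool(p < 0.05),
                "sig_01": bool(p < 0.01),
            }
        )
    return pd.DataFrame(rows)
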