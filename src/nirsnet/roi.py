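"""Region-of-interest analysis: amplitude tables and condition contrasts.

The group-level readout of the block design is the HbO amplitude of each
channel's condition block average at a fixed latency (5 s after task onset,
where the vibrotactile conditions separate from the visual-only one), and
unpaired two-sample t-tests contrasting those amplitudes between
conditions, channel by channel, at alpha = 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BlockAverage

__all__ = [
    "amplitude_at",
    "amplitude_table",
    "contrast_conditions",
    "contrast_table",
    "grand_average",
]

logger = logging.getLogger(__name__)


def amplitude_at(avg: BlockAverage, t: float) -> np.ndarray:
    """Block-average value at the sample nearest ``t`` seconds, per channel."""
    times = avg.times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(
            f"t={t} s outside the epoch span [{times[0]}, {times[-1]}] s"
        )
    idx = int(np.argmin(np.abs(times - t)))
    return avg.data[:, idx].copy()


def amplitude_table(
    subject_averages: dict[int, dict[str, BlockAverage]], t: float = 5.0
) -> pd.DataFrame:
    """Long-format amplitude table: one row per subject x condition x channel.

    ``subject_averages`` maps subject id -> condition -> block average; the
    amplitude column is the block-average HbO at ``t`` s (micromol/L).
    """
    rows = []
    for subject, by_cond in subject_averages.items():
        for condition, avg in by_cond.items():
            amps = amplitude_at(avg, t)
            for ch, hemi, a in zip(avg.channels, avg.hemispheres, amps):
                rows.append((subject, condition, ch, hemi, float(a)))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "channel", "hemisphere", "amplitude"]
    )


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance unpaired t-test, with the degenerate zero-variance
    equal-mean case mapped to (t=0, p=1) by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("zero variance in both groups with equal means; p=1")
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def contrast_conditions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    channel: str,
) -> dict[str, float | str | bool]:
    """Unpaired t-test of HbO amplitude between two conditions at one channel.

    ``table_a``/``table_b`` are amplitude tables (one condition each, one
    row per subject for the channel). Returns the t statistic, two-sided p,
    the direction ("A>B" or "B>A"), and significance flags mirroring the
    ``*``/``**`` convention (p < 0.05 / p < 0.01).
    """
    a = table_a.loc[table_a["channel"] == channel, "amplitude"].to_numpy()
    b = table_b.loc[table_b["channel"] == channel, "amplitude"].to_numpy()
    t, p = _two_sample_t(a, b)
    return {
        "channel": channel,
        "t": t,
        "p": p,
        "direction": "A>B" if t >= 0 else "B>A",
        "sig_05": bool(p < 0.05),
        "sig_01": bool(p < 0.01),
    }


def contrast_table(
    amplitudes: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Channel-by-channel contrast ``cond_a`` vs ``cond_b``.

    No correction for multiple comparisons is applied across channels; each
    channel is tested at its own alpha, as is conventional for exploratory
    per-channel fNIRS reporting. Apply e.g. Bonferroni downstream if a
    family-wise guarantee is needed.
    """
    ta = amplitudes[amplitudes["condition"] == cond_a]
    tb = amplitudes[amplitudes["condition"] == cond_b]
    if channels is None:
        channels = tuple(dict.fromkeys(amplitudes["channel"]))
    rows = [contrast_conditions(ta, tb, ch) for ch in channels]
    df = pd.DataFrame(rows)
    df.insert(0, "contrast", f"{cond_a}>{cond_b}")
    return df


def grand_average(subject_averages: list[BlockAverage]) -> BlockAverage:
    """Across-subject mean of per-subject block averages.

    All inputs must share the epoch grid (tmin, fs, sample count, channel
    order); the dispersion of the result is the across-subject SD.
    """
    if not subject_averages:
        raise ValueError("need at least one subject average")
    first = subject_averages[0]
    for avg in subject_averages[1:]:
        if (
            avg.data.shape != first.data.shape
            or avg.tmin != first.tmin
            or avg.fs != first.fs
            or avg.channels != first.channels
        ):
            raise ValueError("subject averages are on mismatched epoch grids")
    stack = np.stack([a.data for a in subject_averages])
    return BlockAverage(
        data=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        n_blocks=len(subject_averages),
        condition=first.condition,
        tmin=first.tmin,
        fs=first.fs,
        channels=first.channels,
        hemispheres=first.hemispheres,
    )
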