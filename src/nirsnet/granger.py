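"""Bivariate Granger causality and directed cross-hemisphere networks.

For a directed pair y -> x, two autoregressive models are fitted to the
target series x by ordinary least squares on the same sample:

    full:       x_t = a_0 + sum_{i=1..p} a_i x_{t-i} + sum_{i=1..q} b_i y_{t-i} + e_yx(t)
    restricted: x_t = a_0 + sum_{i=1..p} a_i x_{t-i} + e_x(t)

and the Granger-causality value is the log ratio of residual variances,

    G(y -> x) = ln( COV(e_x) / COV(e_yx) ),

which is >= 0 for nested least-squares fits and grows with the predictive
information y's past adds about x. A single joint order p = q is selected
by the Bayesian information criterion on the full model; the Durbin-Watson
statistic of each fit is reported as a residual-autocorrelation diagnostic.

The network stage evaluates all 288 (12 x 12 x 2) directed heterotopic
channel pairs per subject, then screens directed edges whose group GC is
significantly greater than a threshold with a one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BlockAverage, HbTimeSeries
from .laterality import _one_sample_t
from .montage import Montage

__all__ = [
    "ARFit",
    "GCMatrix",
    "CausalNetwork",
    "select_order_bic",
    "gc_value",
    "gc_fits",
    "durbin_watson",
    "gc_heterotopic_matrix",
    "group_edge_test",
    "threshold_sweep",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45)


@dataclass
class ARFit:
    """One least-squares AR fit: coefficients, residuals, diagnostics.

    ``params`` is ordered (intercept, own lags 1..p, cross lags 1..q);
    ``resid_var`` is the biased (1/n) residual variance entering the GC
    ratio; ``bic`` uses the same variance estimate.
    """

    order: int
    params: np.ndarray
    resid: np.ndarray
    resid_var: float
    bic: float

    @property
    def dw(self) -> float:
        return durbin_watson(self.resid)


def _check_series(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"series {name} contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError(f"series {name} is constant: zero-variance regressor")
    return x


def _design(x: np.ndarray, y: np.ndarray | None, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Target x_t and design [1, x lags, (y lags)] aligned at t = order..n-1."""
    n = x.size
    target = x[order:]
    cols = [np.ones(n - order)]
    cols += [x[order - i : n - i] for i in range(1, order + 1)]
    if y is not None:
        cols += [y[order - i : n - i] for i in range(1, order + 1)]
    return target, np.column_stack(cols)


def _ols_fit(target: np.ndarray, design: np.ndarray, order: int) -> ARFit:
    params, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ params
    n_eff = target.size
    var = float(resid @ resid) / n_eff
    # Gaussian log-likelihood BIC with the biased variance estimate.
    k = design.shape[1]
    bic = n_eff * np.log(max(var, 1e-300)) + k * np.log(n_eff)
    return ARFit(order=order, params=params, resid=resid, resid_var=var, bic=float(bic))


def select_order_bic(x: np.ndarray, y: np.ndarray, max_lag: int = 20) -> int:
    """Joint lag order p = q minimising BIC of the full model over 1..max_lag.

    Each candidate order is fitted on its own aligned sample (the first
    ``order`` samples are dropped); ties break toward the smaller order.
    """
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size <= 3 * max_lag:
        raise ValueError(
            f"series of length {x.size} too short for max_lag={max_lag} "
            "(need length > 3 * max_lag)"
        )
    best_order, best_bic = 1, np.inf
    for order in range(1, max_lag + 1):
        target, design = _design(x, y, order)
        fit = _ols_fit(target, design, order)
        if fit.bic < best_bic - 1e-12:
            best_order, best_bic = order, fit.bic
    return best_order


def gc_fits(x: np.ndarray, y: np.ndarray, order: int) -> tuple[ARFit, ARFit]:
    """Restricted and full AR fits of x (both on the sample t = order..n-1)."""
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if order < 1:
        raise ValueError("order must be >= 1")
    if x.size <= 3 * order:
        raise ValueError(
            f"series of length {x.size} too short for order {order}"
        )
    target, design_full = _design(x, y, order)
    restricted = _ols_fit(target, design_full[:, : order + 1], order)
    full = _ols_fit(target, design_full, order)
    return restricted, full


def gc_value(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """Granger causality G(y -> x) = ln(COV(e_x) / COV(e_yx)).

    Both models are least-squares fits on the same sample, so the ratio is
    >= 1 up to rounding; the result is clipped at 0 against floating-point
    noise in the degenerate no-gain case.
    """
    restricted, full = gc_fits(x, y, order)
    if full.resid_var <= 0:
        raise ValueError("full model fits exactly: GC undefined (zero residual)")
    return max(0.0, float(np.log(restricted.resid_var / full.resid_var)))


def durbin_watson(resid: np.ndarray) -> float:
    """Durbin-Watson statistic sum((e_t - e_{t-1})^2) / sum(e_t^2).

    About 2 for uncorrelated residuals, below 2 under positive residual
    autocorrelation, above 2 under negative.
    """
    resid = np.asarray(resid, dtype=float).ravel()
    if resid.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(resid @ resid)
    if denom == 0:
        raise ValueError("all-zero residuals: Durbin-Watson undefined")
    return float(np.sum(np.diff(resid) ** 2) / denom)


@dataclass
class GCMatrix:
    """All directed heterotopic GC values for one subject (one condition).

    ``table`` has one row per ordered cross-hemisphere pair: src, dst,
    src_hemi, dst_hemi, gc, order (288 rows for the default 12+12 montage).
    """

    table: pd.DataFrame
    subject: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        required = {"src", "dst", "src_hemi", "dst_hemi", "gc", "order"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GC table missing columns {sorted(missing)}")
        if (self.table["src_hemi"] == self.table["dst_hemi"]).any():
            raise ValueError("GC table contains a within-hemisphere pair")
        n_left = self.table.loc[self.table["src_hemi"] == "left", "src"].nunique()
        n_right = self.table.loc[self.table["src_hemi"] == "right", "src"].nunique()
        if len(self.table) != 2 * n_left * n_right:
            raise ValueError(
                f"expected {2 * n_left * n_right} directed pairs, got {len(self.table)}"
            )

    def __len__(self) -> int:
        return len(self.table)


def _series_matrix(
    data: BlockAverage | HbTimeSeries, window: tuple[float, float] | None
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(data, BlockAverage):
        series = data.data
        if window is not None:
            times = data.times
            mask = (times >= window[0]) & (times <= window[1] + 1e-9)
            series = series[:, mask]
        return series, data.channels, data.hemispheres
    series = data.hbo
    if window is not None:
        times = data.times
        mask = (times >= window[0]) & (times <= window[1] + 1e-9)
        series = series[:, mask]
    return series, data.channels, data.hemispheres


def gc_heterotopic_matrix(
    data: BlockAverage | HbTimeSeries,
    montage: Montage,
    *,
    window: tuple[float, float] | None = (0.0, 20.0),
    max_lag: int = 20,
    order: int | None = None,
    zscore: bool = True,
    subject: int | None = None,
) -> GCMatrix:
    """GC over every ordered cross-hemisphere channel pair of one subject.

    ``data`` is typically the subject's condition block average, restricted
    to the post-onset ``window``; series are z-scored channel-wise before
    fitting (amplitude scale does not carry directed information). The lag
    order is selected per ordered pair by BIC up to ``max_lag`` unless a
    fixed ``order`` is given. Within-hemisphere pairs are never computed.
    """
    series, channels, hemis = _series_matrix(data, window)
    index = {ch: i for i, ch in enumerate(channels)}
    for ch in montage.channel_names:
        if ch not in index:
            raise ValueError(f"channel {ch} missing from the data")
    if zscore:
        sd = series.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = channels[int(np.argmax(series.std(axis=1) == 0))]
            raise ValueError(f"channel {bad} is constant over the GC window")
        series = (series - series.mean(axis=1, keepdims=True)) / sd

    rows = []
    hemi_of = dict(zip(montage.channel_names, montage.hemispheres))
    for src, dst in montage.heterotopic_pairs():
        xs = series[index[dst]]
        ys = series[index[src]]
        k = select_order_bic(xs, ys, max_lag) if order is None else order
        g = gc_value(xs, ys, k)
        rows.append((src, dst, hemi_of[src], hemi_of[dst], g, k))
    table = pd.DataFrame(
        rows, columns=["src", "dst", "src_hemi", "dst_hemi", "gc", "order"]
    )
    cond = data.condition if isinstance(data, BlockAverage) else None
    return GCMatrix(table=table, subject=subject, condition=cond)


@dataclass
class CausalNetwork:
    """Group-thresholded directed edge set.

    ``table`` holds every directed pair with its group mean GC, t, p and
    edge flag; ``edges`` is the significant subset. Counts partition as
    total = left->right + right->left.
    """

    threshold: float
    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def edges(self) -> pd.DataFrame:
        return self.table[self.table["edge"]].reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return int(self.table["edge"].sum())

    @property
    def n_left_to_right(self) -> int:
        e = self.table
        return int((e["edge"] & (e["src_hemi"] == "left")).sum())

    @property
    def n_right_to_left(self) -> int:
        e = self.table
        return int((e["edge"] & (e["src_hemi"] == "right")).sum())


def group_edge_test(
    matrices: list[GCMatrix],
    threshold: float,
    *,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> CausalNetwork:
    """Screen directed edges whose group GC exceeds a threshold.

    For each directed pair, a one-sample t-test (one-sided "greater" by
    default) compares the subjects' GC values against ``threshold``; pairs
    with p < alpha become edges of the causal network. No multiplicity
    correction is applied across the 288 pairs.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects")
    key = ["src", "dst", "src_hemi", "dst_hemi"]
    base = matrices[0].table[key]
    stacked = np.column_stack(
        [
            m.table.set_index(["src", "dst"]).loc[
                list(zip(base["src"], base["dst"])), "gc"
            ]
            for m in matrices
        ]
    )
    rows = []
    for (src, dst, sh, dh), values in zip(base.itertuples(index=False), stacked):
        t, p = _one_sample_t(values, threshold, alternative)
        rows.append(
            {
                "src": src,
                "dst": dst,
                "src_hemi": sh,
                "dst_hemi": dh,
                "mean_gc": float(np.mean(values)),
                "t": t,
                "p": p,
                "edge": bool(p < alpha),
            }
        )
    return CausalNetwork(threshold=threshold, table=pd.DataFrame(rows), alpha=alpha)


def threshold_sweep(
    matrices: list[GCMatrix],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directed edge counts as a function of the GC threshold.

    Returns one row per threshold: total edges and the left->right /
    right->left split. Counts are non-increasing in the threshold since the
    one-sided selection is nested.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold list must not be empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for th in thresholds:
        net = group_edge_test(matrices, th, alpha=alpha)
        rows.append(
            {
                "threshold": th,
                "total": net.n_edges,
                "left_to_right": net.n_left_to_right,
                "right_to_left": net.n_right_to_left,
            }
        )
    return pd.DataFrame(rows)
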