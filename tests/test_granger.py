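import numpy as np
import pandas as pd
import pytest

from nirsnet import (
    GCMatrix,
    durbin_watson,
    gc_heterotopic_matrix,
    gc_value,
    group_edge_test,
    select_order_bic,
    threshold_sweep,
)
from nirsnet.granger import gc_fits

from conftest import make_block_average


def _lagged_system(n, c, seed, lag=1):
    """x_t = c * y_{t-lag} + e_t with unit-variance white y, e."""
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = np.zeros(n)
    x[lag:] = c * y[:-lag] + e[lag:]
    return x, y


def _normal_equation_gc(x, y, order):
    """Independent oracle: explicit normal-equation regressions."""
    n = x.size
    t = x[order:]
    cols_r = [np.ones(n - order)] + [x[order - i : n - i] for i in range(1, order + 1)]
    cols_f = cols_r + [y[order - i : n - i] for i in range(1, order + 1)]

    def rss(cols):
        X = np.column_stack(cols)
        beta = np.linalg.solve(X.T @ X, X.T @ t)
        r = t - X @ beta
        return float(r @ r)

    return np.log(rss(cols_r) / rss(cols_f))


class TestGcValue:
    def test_independent_white_noise_near_zero(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        assert gc_value(x, y, 1) < 0.01

    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0])
    def test_closed_form_limit(self, c):
        # G(y->x) -> ln(1 + c^2) for x_t = c*y_{t-1} + e_t, unit variances
        x, y = _lagged_system(5000, c, seed=int(c * 10))
        assert gc_value(x, y, 1) == pytest.approx(np.log(1 + c * c), abs=0.05)

    def test_no_reverse_causality(self):
        x, y = _lagged_system(5000, 1.0, seed=21)
        assert gc_value(y, x, 1) < 0.01

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.standard_normal(120)
            y = rng.standard_normal(120)
            assert gc_value(x, y, 3) >= 0.0

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(50):
            n = int(rng.integers(60, 200))
            order = int(rng.integers(1, 4))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            expected = max(0.0, _normal_equation_gc(x, y, order))
            assert gc_value(x, y, order) == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_ssr_ratio(self):
        from statsmodels.tsa.stattools import grangercausalitytests

        x, y = _lagged_system(600, 0.8, seed=5)
        res = grangercausalitytests(np.column_stack([x, y]), maxlag=[2])
        restricted, full = res[2][1][0], res[2][1][1]
        expected = np.log(restricted.ssr / full.ssr)
        assert gc_value(x, y, 2) == pytest.approx(expected, abs=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gc_value(np.ones(100), np.random.default_rng(0).standard_normal(100), 1)

    def test_restricted_variance_at_least_full(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.standard_normal(150)
            y = rng.standard_normal(150)
            restricted, full = gc_fits(x, y, 2)
            assert restricted.resid_var >= full.resid_var - 1e-12


class TestOrderSelection:
    def test_ar1_recovers_order_one_majority(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(1000)
            x = np.zeros(1000)
            for t in range(1, 1000):
                x[t] = 0.8 * x[t - 1] + e[t]
            y = rng.standard_normal(1000)
            if select_order_bic(x, y, max_lag=6) == 1:
                hits += 1
        assert hits >= 15

    def test_white_noise_selects_smallest_order(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        assert select_order_bic(x, y, max_lag=8) == 1

    def test_deterministic_on_rerun(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        assert select_order_bic(x, y, 10) == select_order_bic(x, y, 10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            select_order_bic(np.arange(30.0), np.arange(30.0) ** 2, max_lag=20)


class TestDurbinWatson:
    def test_white_noise_near_two(self):
        resid = np.random.default_rng(0).standard_normal(2000)
        assert durbin_watson(resid) == pytest.approx(2.0, abs=0.1)

    def test_alternating_residuals_near_four(self):
        resid = np.tile([1.0, -1.0], 500)
        assert durbin_watson(resid) == pytest.approx(4.0, abs=0.01)

    def test_smooth_ramp_near_zero(self):
        assert durbin_watson(np.linspace(1.0, 2.0, 500)) < 0.1

    def test_matches_statsmodels(self):
        from statsmodels.stats.stattools import durbin_watson as sm_dw

        resid = np.random.default_rng(5).standard_normal(300)
        assert durbin_watson(resid) == pytest.approx(float(sm_dw(resid)), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            durbin_watson(np.zeros(10))


def _noise_average(montage, seed, n=200, couplings=()):
    """White-noise 24-channel pseudo block average with optional lag couplings."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((24, n))
    idx = {ch: i for i, ch in enumerate(montage.channel_names)}
    for src, dst, lag, gain in couplings:
        data[idx[dst], lag:] += gain * data[idx[src], :-lag]
    return make_block_average(data, montage, tmin=0.0)


class TestHeterotopicMatrix:
    def test_288_entries_cross_hemisphere_only(self, montage):
        m = gc_heterotopic_matrix(_noise_average(montage, 0), montage,
                                  window=None, max_lag=3)
        assert len(m) == 288
        assert (m.table["src_hemi"] != m.table["dst_hemi"]).all()

    def test_null_matrix_small_values(self, montage):
        m = gc_heterotopic_matrix(_noise_average(montage, 1), montage,
                                  window=None, max_lag=3)
        assert m.table["gc"].max() < 0.05

    def test_injected_coupling_is_matrix_maximum(self, montage):
        avg = _noise_average(
            montage, 2, couplings=[("S3_D1", "S8_D5", 1, 1.0)]
        )
        m = gc_heterotopic_matrix(avg, montage, window=None, max_lag=3)
        top = m.table.loc[m.table["gc"].idxmax()]
        assert (top["src"], top["dst"]) == ("S3_D1", "S8_D5")

    def test_missing_channel_named(self, montage):
        avg = _noise_average(montage, 3)
        avg.channels = avg.channels[:-1] + ("X9_D9",)
        with pytest.raises(ValueError, match="S5_D4"):
            gc_heterotopic_matrix(avg, montage, window=None, max_lag=3)

    def test_table_shape_validation(self):
        bad = pd.DataFrame(
            {"src": ["a"], "dst": ["b"], "src_hemi": ["left"],
             "dst_hemi": ["left"], "gc": [0.1], "order": [1]}
        )
        with pytest.raises(ValueError, match="within-hemisphere"):
            GCMatrix(table=bad)


def _constant_matrices(montage, per_pair_values, n_subjects=None):
    """Build subject GCMatrix list from {(src, dst): [subject values]}."""
    pairs = list(montage.heterotopic_pairs())
    hemi = dict(zip(montage.channel_names, montage.hemispheres))
    if n_subjects is None:
        n_subjects = (
            len(next(iter(per_pair_values.values()))) if per_pair_values else 5
        )
    matrices = []
    for s in range(n_subjects):
        rows = [
            (src, dst, hemi[src], hemi[dst],
             per_pair_values.get((src, dst), [0.0] * n_subjects)[s], 1)
            for src, dst in pairs
        ]
        matrices.append(
            GCMatrix(
                table=pd.DataFrame(
                    rows,
                    columns=["src", "dst", "src_hemi", "dst_hemi", "gc", "order"],
                ),
                subject=s,
            )
        )
    return matrices


class TestGroupEdges:
    def test_all_zero_gives_empty_network(self, montage):
        nets = group_edge_test(_constant_matrices(montage, {}), threshold=0.3)
        assert nets.n_edges == 0

    def test_single_strong_pair_is_sole_edge(self, montage):
        rng = np.random.default_rng(0)
        values = {("S3_D1", "S8_D5"): list(0.8 + 0.01 * rng.standard_normal(14))}
        net = group_edge_test(_constant_matrices(montage, values), threshold=0.3)
        assert net.n_edges == 1
        edge = net.edges.iloc[0]
        assert (edge["src"], edge["dst"]) == ("S3_D1", "S8_D5")

    def test_counts_partition(self, montage):
        rng = np.random.default_rng(1)
        values = {
            ("S3_D1", "S8_D5"): list(0.8 + 0.01 * rng.standard_normal(6)),
            ("S8_D7", "S3_D2"): list(0.9 + 0.01 * rng.standard_normal(6)),
        }
        net = group_edge_test(_constant_matrices(montage, values), threshold=0.3)
        assert net.n_edges == net.n_left_to_right + net.n_right_to_left
        assert net.n_left_to_right == 1 and net.n_right_to_left == 1


class TestThresholdSweep:
    def _matrices(self, montage):
        rng = np.random.default_rng(5)
        values = {}
        for k, (src, dst) in enumerate(list(montage.heterotopic_pairs())[:20]):
            level = 0.1 + 0.04 * k
            values[(src, dst)] = list(level + 0.01 * rng.standard_normal(8))
        return _constant_matrices(montage, values)

    def test_counts_nonincreasing_and_partition(self, montage):
        sweep = threshold_sweep(self._matrices(montage))
        totals = sweep["total"].to_numpy()
        assert np.all(np.diff(totals) <= 0)
        assert (sweep["total"] == sweep["left_to_right"] + sweep["right_to_left"]).all()

    def test_threshold_above_everything_gives_zero(self, montage):
        sweep = threshold_sweep(self._matrices(montage), thresholds=(5.0,))
        assert sweep.loc[0, "total"] == 0

    def test_empty_threshold_list_rejected(self, montage):
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(self._matrices(montage), thresholds=())

    def test_unsorted_thresholds_rejected(self, montage):
        with pytest.raises(ValueError, match="sorted"):
            threshold_sweep(self._matrices(montage), thresholds=(0.4, 0.2))


class TestDirectionRecovery:
    def test_planted_driver_beats_reverse_in_19_of_20_seeds(self):
        wins = 0
        for seed in range(20):
            x, y = _lagged_system(1000, 1.0, seed=seed)
            if gc_value(x, y, 1) > gc_value(y, x, 1):
                wins += 1
        assert wins >= 19
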