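"""Filters, normalization, ComBat, day differencing, variance filter."""

import numpy as np
import pandas as pd
import pytest

from mscpotency.core import ValidationError
from mscpotency.preprocess import (
    autoscale,
    blank_qc_filter,
    combat_correct,
    day_difference,
    median_normalize,
    rsd_filter,
    variance_filter_select,
)
from mscpotency.synth import SyntheticSpec, generate_study

from conftest import make_table


class TestBlankQCFilter:
    def _table(self, exp_vals, blank_vals, qc_vals):
        vals = np.vstack([exp_vals, blank_vals, qc_vals])
        roles = (["experimental"] * len(exp_vals) + ["blank"] * len(blank_vals)
                 + ["qc_pool"] * len(qc_vals))
        return make_table(vals, roles=roles)

    def test_five_fold_rule(self):
        # f1: mean 10 vs blank 1 -> kept; f2: mean 4 vs blank 1 -> removed
        t = self._table([[10.0, 4.0], [10.0, 4.0]], [[1.0, 1.0]], [[10.0, 4.0]])
        out, report = blank_qc_filter(t)
        assert out.feature_ids == ["f1"]
        assert report.removed == ["f2"]
        report.check_partition(t.feature_ids)

    def test_qc_presence_rule(self):
        # f2 present in only 1 of 4 QC injections
        exp = [[10.0, 10.0]] * 2
        qc = [[10.0, 10.0], [10.0, 0.0], [10.0, 0.0], [10.0, 0.0]]
        t = self._table(exp, [[0.1, 0.1]], qc)
        out, report = blank_qc_filter(t, qc_presence=0.5)
        assert report.removed == ["f2"]

    def test_blanks_and_qcs_retained_for_audit(self):
        t = self._table([[10.0]], [[1.0]], [[10.0]])
        out, _ = blank_qc_filter(t)
        assert sorted(out.sample_meta["role"].unique()) == [
            "blank", "experimental", "qc_pool"]

    def test_requires_blanks_and_qcs(self):
        t = make_table([[1.0], [2.0]])
        with pytest.raises(ValidationError, match="blank"):
            blank_qc_filter(t)


class TestRSDFilter:
    def test_constant_feature_removed_by_default(self):
        t = make_table([[5.0, 1.0], [5.0, 3.0]])
        out, report = rsd_filter(t)
        assert report.removed == ["f1"]  # RSD 0 < 0.25

    def test_hand_arithmetic_kept(self):
        # values {1,3}: mean 2, sd sqrt(2), RSD ~ 0.707 -> kept under default
        t = make_table([[1.0], [3.0]])
        out, _ = rsd_filter(t)
        assert out.feature_ids == ["f1"]

    def test_remove_above_mode(self):
        t = make_table([[1.0], [3.0]])
        out, _ = rsd_filter(t, threshold=0.25, mode="remove_above")
        assert out.feature_ids == []

    def test_zero_mean_feature_removed_in_both_modes(self):
        vals = np.array([[1.0, 0.0], [3.0, 0.0]])
        t = make_table(vals, stage="raw")
        for mode in ("remove_below", "remove_above"):
            _, report = rsd_filter(t, mode=mode)
            assert "f2" in report.removed


class TestMedianNormalize:
    def test_scale_invariance(self):
        base = np.array([1.0, 2.0, 5.0, 9.0])
        t = make_table(np.vstack([base, 2.0 * base]))
        out = median_normalize(t)
        assert np.allclose(out.values.iloc[0], out.values.iloc[1])

    def test_single_sample_unchanged(self):
        t = make_table([[1.0, 2.0, 3.0]])
        out = median_normalize(t)
        assert np.allclose(out.values.to_numpy(), t.values.to_numpy())

    def test_sample_medians_equalized(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.lognormal(size=(5, 10)))
        out = median_normalize(t)
        med = out.values.median(axis=1)
        assert np.allclose(med, med.iloc[0])

    def test_zero_median_sample_rejected(self):
        t = make_table([[0.0, 0.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError, match="median 0"):
            median_normalize(t)


class TestAutoscale:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.lognormal(size=(6, 4)))
        out = autoscale(t)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_feature_zeroed(self):
        t = make_table([[3.0, 1.0], [3.0, 2.0], [3.0, 4.0]])
        out = autoscale(t)
        assert (out.values["f1"] == 0.0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.lognormal(size=(5, 3)))
        once = autoscale(t)
        twice = autoscale(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)


class TestComBat:
    def test_single_batch_fixed_point(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.lognormal(size=(6, 5)))
        out = combat_correct(t)
        assert np.allclose(out.values.to_numpy(), t.values.to_numpy(), atol=1e-9)

    def test_pure_location_shift_removed(self):
        """Two batches differing by +delta on every feature: the between-batch
        mean difference collapses after correction."""
        rng = np.random.default_rng(4)
        n, p, delta = 40, 60, 10.0
        base = rng.normal(10.0, 1.0, (2 * n, p))
        base[n:] += delta
        batches = ["B1"] * n + ["B2"] * n
        t = make_table(base, batches=batches, stage="filtered")
        out = combat_correct(t)
        before = base[n:].mean(axis=0) - base[:n].mean(axis=0)
        v = out.values.to_numpy()
        after = v[n:].mean(axis=0) - v[:n].mean(axis=0)
        assert (np.abs(after) <= 0.05 * np.abs(before)).all()

    def test_scale_factor_equalized(self):
        """Batch-2 SD inflated 2x: post-correction per-batch SDs agree."""
        rng = np.random.default_rng(5)
        n, p = 40, 80
        a = rng.normal(0.0, 1.0, (n, p))
        b = rng.normal(0.0, 2.0, (n, p))
        t = make_table(np.vstack([a, b]) + 50.0,
                       batches=["B1"] * n + ["B2"] * n, stage="filtered")
        out = combat_correct(t)
        v = out.values.to_numpy()
        ratio = v[n:].std(axis=0, ddof=1) / v[:n].std(axis=0, ddof=1)
        assert (np.abs(np.log(ratio)) <= np.log(1.25)).mean() >= 0.95

    def test_small_batch_rejected(self):
        t = make_table(np.ones((3, 2)) + np.arange(6).reshape(3, 2),
                       batches=["B1", "B1", "B2"])
        with pytest.raises(ValidationError, match="ComBat needs"):
            combat_correct(t)

    def test_matches_reference_implementation(self):
        """Cross-check against scanpy's ComBat on a random two-batch table."""
        sc = pytest.importorskip("scanpy")
        import anndata

        rng = np.random.default_rng(6)
        n, p = 12, 25
        X = rng.normal(5.0, 1.0, (2 * n, p))
        X[n:] = X[n:] * 1.5 + 2.0
        t = make_table(X + 20.0, batches=["B1"] * n + ["B2"] * n, stage="filtered")
        ours = combat_correct(t).values.to_numpy()
        ad = anndata.AnnData(
            X=t.values.to_numpy().astype(np.float64),
            obs=pd.DataFrame({"batch": ["B1"] * n + ["B2"] * n},
                             index=t.values.index.astype(str)),
        )
        sc.pp.combat(ad, key="batch")
        assert np.allclose(ours, ad.X, rtol=1e-3, atol=1e-3)


class TestDayDifference:
    def _nmr(self, day_values):
        """day_values: dict day -> list of per-flask values for one feature."""
        rows, roles, lines, days, reps = [], [], [], [], []
        for day, vals in day_values.items():
            for r, v in enumerate(vals):
                rows.append([v])
                lines.append(f"L{r + 1}")
                days.append(day)
                reps.append("r01")
        t = make_table(np.array(rows), lines=lines, day=days, stage="raw")
        t.sample_meta["replicate_id"] = reps
        return t

    def test_constant_trajectory_zero(self):
        t = self._nmr({1: [4.0, 4.0], 3: [4.0, 4.0]})
        out = day_difference(t, target_day=3)
        assert np.allclose(out.values.to_numpy(), 0.0)
        assert out.stage == "differenced"

    def test_arithmetic(self):
        t = self._nmr({1: [2.0], 3: [7.0]})
        out = day_difference(t, target_day=3)
        assert out.values.iloc[0, 0] == 5.0

    def test_unmatched_flask_rejected(self):
        t = self._nmr({1: [2.0, 3.0], 3: [7.0]})
        with pytest.raises(ValidationError, match="lacks a sample"):
            day_difference(t, target_day=3)

    def test_nonmonotonic_trajectory_signs(self):
        """Generator trajectories that rise then fall below baseline give
        positive day-2 and negative day-3 differences (noise-free)."""
        spec = SyntheticSpec(
            seed=9, effect_size=0.0, donor_noise_sd=0.0, replicate_noise_sd=0.0,
            batch_location_shift=0.0, batch_scale_factor=1.0,
            n_features={"ms_lipid": 5, "ms_polar": 5, "nmr": 30},
            n_informative={"ms_lipid": 0, "ms_polar": 0, "nmr": 0},
            n_replicates_nmr=2,
        )
        _, _, nmr, _, _ = generate_study(spec)
        log_table = nmr.with_values(np.log(nmr.values), stage="filtered")
        nonmono = nmr.feature_meta.index[nmr.feature_meta["trajectory"] == "non_monotonic"]
        d2 = day_difference(log_table, target_day=2)
        d3 = day_difference(log_table, target_day=3)
        assert (d2.values[nonmono].to_numpy() > 0).all()
        assert (d3.values[nonmono].to_numpy() < 0).all()

    def test_difference_commutes_with_line_aggregation(self):
        spec = SyntheticSpec(
            seed=10, n_features={"ms_lipid": 5, "ms_polar": 5, "nmr": 20},
            n_informative={"ms_lipid": 0, "ms_polar": 0, "nmr": 2},
            n_replicates_nmr=4,
        )
        _, _, nmr, _, _ = generate_study(spec)
        diff_then_agg = day_difference(nmr, target_day=3).aggregate_by_line()
        by_day = {
            d: nmr.subset_samples(
                nmr.sample_meta.index[nmr.sample_meta["day"] == d]
            ).aggregate_by_line()
            for d in (1, 3)
        }
        agg_then_diff = by_day[3] - by_day[1]
        assert np.allclose(diff_then_agg.to_numpy(), agg_then_diff.to_numpy(), atol=1e-9)


class TestVarianceFilterSelect:
    def test_informative_feature_selected(self):
        rng = np.random.default_rng(7)
        n = 10
        y = pd.Series(rng.normal(size=n), index=[f"L{i}" for i in range(n)])
        X = pd.DataFrame(rng.normal(0, 0.2, (n, 30)), index=y.index,
                         columns=[f"f{j}" for j in range(30)])
        X["f0"] = 3.0 * y  # high variance AND predictive
        subset, frac, scores = variance_filter_select(X, y, (0.1, 0.5, 1.0))
        assert "f0" in subset.columns
        assert scores[frac] == max(scores.values())

    def test_all_noise_low_loo_r2(self):
        vals = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n = 10
            y = pd.Series(rng.normal(size=n), index=[f"L{i}" for i in range(n)])
            X = pd.DataFrame(rng.normal(size=(n, 40)), index=y.index)
            X.columns = [f"f{j}" for j in range(40)]
            _, frac, scores = variance_filter_select(X, y, (0.1, 0.5, 1.0))
            vals.append(scores[frac])
        assert np.median(vals) <= 0.3

    def test_full_grid_point_returns_everything(self):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=8), index=[f"L{i}" for i in range(8)])
        X = pd.DataFrame(rng.normal(size=(8, 12)), index=y.index,
                         columns=[f"f{j}" for j in range(12)])
        subset, frac, _ = variance_filter_select(X, y, (1.0,))
        assert frac == 1.0 and subset.shape == X.shape

    def test_empty_grid_rejected(self):
        y = pd.Series(np.arange(5.0), index=list("abcde"))
        X = pd.DataFrame(np.eye(5), index=y.index)
        with pytest.raises(ValidationError, match="non-empty"):
            variance_filter_select(X, y, ())
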