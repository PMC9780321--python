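"""Tests of the spike-in benchmark generator."""

import numpy as np
import pytest

from rolde import (
    CATEGORIES,
    NoiseConfig,
    enumerate_benchmark,
    benchmark_plan,
    filter_complete,
    generate_dataset,
    inject_missing,
    trend_profile,
)


class TestTrendProfiles:
    def test_linear_ramps_across_all_levels(self):
        np.testing.assert_array_equal(trend_profile("Linear", "up", 5, 5), [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(trend_profile("Linear", "down", 5, 5), [5, 4, 3, 2, 1])

    def test_stable_constant_mid_level(self):
        np.testing.assert_array_equal(trend_profile("Stable", "up", 5, 5), [3] * 5)

    def test_poly2_single_interior_extremum(self):
        seq = trend_profile("Poly2", "up", 5, 5)
        np.testing.assert_array_equal(seq, [5, 3, 1, 3, 5])
        diffs = np.sign(np.diff(seq))
        changes = (np.diff(diffs[diffs != 0]) != 0).sum()
        assert changes == 1

    def test_loglike_concave_monotone(self):
        seq = trend_profile("LogLike", "up", 5, 5)
        assert (np.diff(seq) >= 0).all()
        steps = np.diff(seq.astype(float))
        assert steps[0] >= steps[-1]  # early steps large, plateau at end
        assert seq[0] == 1 and seq[-1] == 5

    def test_sigmoid_plateau_steep_plateau(self):
        seq = trend_profile("Sigmoid", "up", 5, 5)
        steps = np.abs(np.diff(seq.astype(float)))
        assert steps.argmax() in (1, 2)
        assert seq[0] == seq[1] or seq[-1] == seq[-2]

    def test_polyhigher_two_interior_direction_changes(self):
        for T in (5, 7, 10):
            seq = trend_profile("PolyHigher", "up", T, 5)
            diffs = np.sign(np.diff(seq.astype(float)))
            diffs = diffs[diffs != 0]
            assert (np.diff(diffs) != 0).sum() >= 2

    def test_reduced_designs_truncate_from_front(self):
        full = trend_profile("Linear", "up", 5, 5)
        np.testing.assert_array_equal(trend_profile("Linear", "up", 4, 5), full[1:])
        np.testing.assert_array_equal(trend_profile("Linear", "up", 3, 5), full[2:])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown trend category"):
            trend_profile("Exponential", "up", 5, 5)


class TestEnumeration:
    def test_six_categories_give_21_combinations(self):
        assert len(enumerate_benchmark(CATEGORIES)) == 21

    def test_five_categories_give_15_combinations(self):
        assert len(enumerate_benchmark(tuple(c for c in CATEGORIES if c != "Linear"))) == 15

    def test_single_category(self):
        assert enumerate_benchmark(("Stable",)) == [("Stable", "Stable")]

    def test_null_pair_exclusion(self):
        combos = enumerate_benchmark(CATEGORIES, exclude_null_pair=True)
        assert len(combos) == 20 and ("Stable", "Stable") not in combos

    def test_full_benchmark_inventory(self):
        plan = benchmark_plan()
        assert plan["n_datasets"].sum() == 3120


class TestGeneration:
    def test_seed_reproducibility(self):
        a = generate_dataset(n_background=30, n_spikein=5, seed=42)
        b = generate_dataset(n_background=30, n_spikein=5, seed=42)
        np.testing.assert_array_equal(a.expr.values, b.expr.values)

    def test_zero_noise_limit(self):
        noise = NoiseConfig(sigma_median=1e-12, sigma_log_sd=1e-12)
        ds = generate_dataset(n_background=10, n_spikein=5, noise=noise, seed=0)
        for sid in ds.expr.samples:
            row = ds.design.table.set_index("sample_id").loc[sid]
            gcol = f"{row['condition']}_t{int(row['timepoint'])}"
            np.testing.assert_allclose(
                ds.expr.frame[sid].to_numpy(), ds.mu[gcol].to_numpy(), atol=1e-6
            )

    def test_stable_stable_has_no_true_positives_in_means(self):
        ds = generate_dataset(
            n_background=20, n_spikein=5, trend_pair=("Stable", "Stable"), seed=1
        )
        mu = ds.mu.to_numpy()
        np.testing.assert_allclose(mu, np.broadcast_to(mu[:, [0]], mu.shape), atol=1e-12)

    def test_group_means_within_three_standard_errors(self):
        """With 3 replicates per group, >= 99% of group sample means land
        within 3 SE of the generative mean."""
        ds = generate_dataset(n_background=1000, n_spikein=50, seed=2)
        design = ds.design.table.set_index("sample_id")
        ok = 0
        total = 0
        for gcol in ds.mu.columns:
            cond, tlab = gcol.rsplit("_t", 1)
            sids = [
                s for s in ds.expr.samples
                if design.loc[s, "condition"] == cond
                and int(design.loc[s, "timepoint"]) == int(tlab)
            ]
            vals = ds.expr.frame[sids].to_numpy()
            se = ds.sigma[gcol].to_numpy() / np.sqrt(len(sids))
            dev = np.abs(vals.mean(axis=1) - ds.mu[gcol].to_numpy())
            ok += (dev <= 3 * se).sum()
            total += len(dev)
        assert ok / total >= 0.99

    def test_spikein_truth_labels(self):
        ds = generate_dataset(n_background=10, n_spikein=4, trend_pair=("Linear", "Sigmoid"), seed=3)
        assert ds.truth["is_spikein"].sum() == 4
        spikes = ds.truth[ds.truth["is_spikein"]]
        assert set(spikes["trend_c1"]) == {"Linear"} and set(spikes["trend_c2"]) == {"Sigmoid"}

    def test_excess_spikeins_warn(self):
        with pytest.warns(UserWarning, match="unrealistic"):
            generate_dataset(n_background=5, n_spikein=10, seed=4)


class TestMissingness:
    def test_zero_rate_identity(self):
        ds = generate_dataset(n_background=20, n_spikein=2, seed=5)
        out = inject_missing(ds, 0.0, seed=6)
        np.testing.assert_array_equal(out.expr.values, ds.expr.values)

    def test_mcar_realized_rate(self):
        ds = generate_dataset(n_background=4000, n_spikein=0, seed=7)  # 1.2e5 cells
        out = inject_missing(ds, 0.2, mechanism="MCAR", seed=8)
        rate = np.isnan(out.expr.values).mean()
        assert rate == pytest.approx(0.2, abs=0.005)

    def test_mnar_left_censoring(self):
        ds = generate_dataset(n_background=2000, n_spikein=0, seed=9)
        out = inject_missing(ds, 0.2, mechanism="MNAR", seed=10)
        vals = ds.expr.values
        miss = np.isnan(out.expr.values)
        assert vals[miss].mean() < vals[~miss].mean()
        assert miss.mean() == pytest.approx(0.2, abs=0.01)

    def test_separate_spikein_rate(self):
        ds = generate_dataset(n_background=2000, n_spikein=200, seed=11)
        out = inject_missing(ds, 0.195, spikein_rate=0.294, mechanism="MNAR", seed=12)
        spike = out.truth["is_spikein"].to_numpy()
        rate_bg = np.isnan(out.expr.values[~spike]).mean()
        rate_sp = np.isnan(out.expr.values[spike]).mean()
        assert rate_bg == pytest.approx(0.195, abs=0.015)
        assert rate_sp == pytest.approx(0.294, abs=0.03)

    def test_invalid_rate_rejected(self):
        ds = generate_dataset(n_background=5, n_spikein=1, seed=13)
        with pytest.raises(ValueError, match="rates"):
            inject_missing(ds, 1.2, seed=14)


class TestFilterComplete:
    def test_identity_without_missing(self):
        ds = generate_dataset(n_background=15, n_spikein=3, seed=15)
        out = filter_complete(ds)
        assert out.expr.proteins == ds.expr.proteins

    def test_single_missing_cell_removes_protein(self):
        ds = generate_dataset(n_background=15, n_spikein=3, seed=16)
        vals = ds.expr.values.copy()
        vals[4, 7] = np.nan
        ds2 = ds.__class__(
            expr=type(ds.expr).from_frame(
                ds.expr.frame.copy().where(~np.isnan(vals) | np.isnan(ds.expr.values), np.nan)
            ),
            design=ds.design, truth=ds.truth, mu=ds.mu, sigma=ds.sigma,
        )
        ds2.expr.frame.iloc[4, 7] = np.nan
        out = filter_complete(ds2)
        assert ds.expr.proteins[4] not in out.expr.proteins
        assert len(out.expr.proteins) == 17

    def test_survivor_count_matches_row_scan_oracle(self):
        ds = generate_dataset(n_background=200, n_spikein=20, seed=17)
        ds = inject_missing(ds, 0.1, mechanism="MCAR", seed=18)
        out = filter_complete(ds)
        expected = int(np.isfinite(ds.expr.values).all(axis=1).sum())
        assert len(out.expr.proteins) == expected
        assert len(out.truth) == expected
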