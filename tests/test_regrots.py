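"""Tests of the per-individual regression module: degree rule, orthogonal
basis, individual fits, run pairing and the rank-product score."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rolde import (
    fit_individual_models,
    orthogonal_basis,
    pair_runs,
    regrots_degree,
    regrots_score,
)
from rolde.rots import RotsSettings

from conftest import make_design, make_expression


@pytest.mark.parametrize("m,expected", [(5, 2), (8, 4), (2, 1), (3, 1), (4, 2), (10, 4), (20, 4)])
def test_degree_rule(m, expected):
    assert regrots_degree(m) == expected


def test_degree_rule_rejects_short_series():
    with pytest.raises(ValueError, match="too few time points"):
        regrots_degree(1)


class TestOrthogonalBasis:
    def test_equispaced_grid_matches_classical_contrasts(self):
        b = orthogonal_basis(np.arange(1.0, 6.0), 2, scale=False)
        np.testing.assert_allclose(b[:, 0], [-2, -1, 0, 1, 2], atol=1e-12)
        np.testing.assert_allclose(b[:, 1], [2, -1, -2, -1, 2], atol=1e-12)

    def test_three_point_linear_scaled(self):
        b = orthogonal_basis(np.array([1.0, 2.0, 3.0]), 1, scale=True)
        np.testing.assert_allclose(b[:, 0], np.array([-1, 0, 1]) / np.sqrt(2), atol=1e-12)

    def test_scaled_basis_is_orthonormal(self):
        t = np.array([0.0, 0.5, 1.7, 3.0, 4.2, 9.0])
        b = orthogonal_basis(t, 3, scale=True)
        np.testing.assert_allclose(b.T @ b, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(b.sum(axis=0), 0.0, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=-50, max_value=50),
            min_size=4,
            max_size=9,
            unique=True,
        ),
        st.integers(min_value=1, max_value=3),
    )
    def test_matches_gram_schmidt_oracle(self, t, degree):
        """Columns span the same flags as Gram-Schmidt on the monomial basis
        and are proportional to its output, column by column."""
        t = np.asarray(sorted(t))
        b = orthogonal_basis(t, degree, scale=True)
        # independent oracle: QR of the Vandermonde matrix
        v = np.vander(t, degree + 1, increasing=True)
        q, _ = np.linalg.qr(v)
        oracle = q[:, 1:]
        for j in range(degree):
            ratio = b[:, j] @ oracle[:, j]
            np.testing.assert_allclose(b[:, j], ratio * oracle[:, j], atol=1e-8)

    def test_degree_too_high(self):
        with pytest.raises(ValueError, match="degree too high"):
            orthogonal_basis(np.array([1.0, 2.0, 3.0]), 3)


class TestIndividualFits:
    def test_constant_series_exact(self):
        design = make_design(2)
        vals = np.full((3, len(design.sample_ids)), 7.0)
        coef, _ = fit_individual_models(make_expression(design, vals), design, 2)
        np.testing.assert_allclose(coef[:, :, 0], 7.0, atol=1e-10)
        np.testing.assert_allclose(coef[:, :, 1:], 0.0, atol=1e-10)

    def test_recovers_planted_slope(self):
        design = make_design(2)
        basis = orthogonal_basis(design.timepoints, 1, scale=True)
        vals = np.zeros((2, len(design.sample_ids)))
        # protein 0: y = 3 + 1.5 * P1(t) for every individual
        for i, sid in enumerate(design.sample_ids):
            tp = float(design.table.set_index("sample_id").loc[sid, "timepoint"])
            ti = list(design.timepoints).index(tp)
            vals[0, i] = 3.0 + 1.5 * basis[ti, 0]
        coef, _ = fit_individual_models(make_expression(design, vals), design, 1)
        np.testing.assert_allclose(coef[0, :, 0], 3.0, atol=1e-10)
        np.testing.assert_allclose(coef[0, :, 1], 1.5, atol=1e-10)

    def test_underdetermined_fit_invalid(self):
        design = make_design(2)
        vals = np.random.default_rng(0).normal(size=(1, len(design.sample_ids)))
        # first individual keeps only d = 2 observations: one too few for d + 1
        ind = design.individuals("C1")[0]
        cols = [i for i, s in enumerate(design.sample_ids) if s.startswith(ind)]
        vals[0, cols[3:]] = np.nan
        vals[0, cols[0]] = np.nan
        coef, individuals = fit_individual_models(make_expression(design, vals), design, 2)
        assert np.isnan(coef[0, individuals.index(ind), :]).all()
        assert np.isfinite(coef[0, 1:, :]).all()


class TestRunPairing:
    def test_three_vs_three_worked_example(self):
        runs = pair_runs(["u1", "u2", "u3"], ["v1", "v2", "v3"])
        assert runs == [
            [("u1", "v1"), ("u2", "v2"), ("u3", "v3")],
            [("u1", "v2"), ("u2", "v3"), ("u3", "v1")],
            [("u1", "v3"), ("u2", "v1"), ("u3", "v2")],
        ]

    def test_one_vs_one(self):
        assert pair_runs(["u"], ["v"]) == [[("u", "v")]]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_equal_sizes_exhaustive_coverage(self, n):
        us = [f"u{i}" for i in range(n)]
        vs = [f"v{i}" for i in range(n)]
        runs = pair_runs(us, vs)
        assert len(runs) == n
        all_pairs = [p for run in runs for p in run]
        assert len(all_pairs) == len(set(all_pairs)) == n * n
        for run in runs:
            assert len({u for u, _ in run}) == n
            assert len({v for _, v in run}) == n

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 5), (1, 4)])
    def test_unequal_sizes(self, n1, n2):
        us = [f"u{i}" for i in range(n1)]
        vs = [f"v{i}" for i in range(n2)]
        runs = pair_runs(us, vs)
        assert len(runs) == max(n1, n2)
        all_pairs = [p for run in runs for p in run]
        assert len(all_pairs) == len(set(all_pairs)) == n1 * n2
        for run in runs:
            assert all(u in us and v in vs for u, v in run)
            assert len({u for u, _ in run}) == len(run)
            assert len({v for _, v in run}) == len(run)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pair_runs([], ["v"])


class TestRegrotsScore:
    SETTINGS = RotsSettings(b=20, k_grid=[10, 25], n_perm=50)

    def test_score_is_geometric_mean_of_run_ranks(self, design_3v3, null_expression):
        res = regrots_score(
            null_expression, design_3v3, settings=self.SETTINGS, seed=3
        )
        ranks = res.extra["run_ranks"]
        for p in range(0, 200, 17):
            valid = np.isfinite(ranks[p])
            expected = float(np.prod(ranks[p, valid]) ** (1.0 / valid.sum()))
            assert res.scores[p] == pytest.approx(expected, rel=1e-12)
        assert np.nanmin(res.scores) >= 1.0
        assert np.nanmax(res.scores) <= 200.0

    def test_null_run_pvalues_approximately_uniform(self):
        design = make_design(3)
        rng = np.random.default_rng(77)
        n = 500
        vals = rng.normal(25, 2, size=(n, 1))[:, [0] * len(design.sample_ids)]
        vals = vals + rng.normal(0, 0.3, size=(n, len(design.sample_ids)))
        res = regrots_score(
            make_expression(design, vals), design,
            settings=RotsSettings(b=20, k_grid=[25, 50], n_perm=None), seed=4,
        )
        for r in range(res.run_pvalues.shape[1]):
            p = res.run_pvalues[:, r]
            ks = stats.kstest(p[np.isfinite(p)], "uniform").statistic
            assert ks < 0.15

    def test_slope_only_difference_detected(self):
        """Proteins whose conditions differ only in the linear trend get
        RegROTS scores below the null median (Mann-Whitney p < 0.01)."""
        design = make_design(3)
        rng = np.random.default_rng(88)
        n, n_aff = 500, 50
        ns = len(design.sample_ids)
        vals = rng.normal(25, 2, size=(n, 1))[:, [0] * ns] + rng.normal(0, 0.3, size=(n, ns))
        tps = design.table["timepoint"].to_numpy()
        c2 = (design.table["condition"] == "C2").to_numpy()
        slope = 0.4 * (tps - tps.mean())
        vals[:n_aff, :] += np.where(c2, slope, 0.0)[None, :]
        res = regrots_score(
            make_expression(design, vals), design,
            settings=RotsSettings(b=20, k_grid=[25, 50]), seed=5,
        )
        mw = stats.mannwhitneyu(res.scores[:n_aff], res.scores[n_aff:], alternative="less")
        assert mw.pvalue < 0.01
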