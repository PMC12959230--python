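"""CV^2 / effect statistics and the correlation screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import sepalvar as sv
from sepalvar import stats as rs
from sepalvar._errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)


class TestSummarize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 5], (5.0, 0.0, 0.0)),
            ([1, 2, 3], (2.0, 1.0, 0.25)),
            ([2, 4, 6], (4.0, 2.0, 0.25)),  # CV^2 is scale invariant
        ],
    )
    def test_hand_computed_values(self, values, expected):
        mean, sd, cv2 = sv.summarize(values)
        assert (mean, sd, cv2) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            sv.summarize([1.0])
        with pytest.raises(InvalidInputError):
            sv.summarize([-1.0, -2.0, -3.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=30),
        c=st.floats(1e-3, 1e4),
    )
    def test_cv2_scale_invariance(self, values, c):
        _, _, cv2 = sv.summarize(values)
        _, _, cv2_scaled = sv.summarize([c * v for v in values])
        assert cv2_scaled == pytest.approx(cv2, rel=1e-9, abs=1e-12)

    def test_agrees_with_two_pass_oracle(self):
        """summarize matches an explicit two-pass mean/variance loop to 1e-12."""
        rng = np.random.default_rng(1)
        v = rng.gamma(5.0, 2.0, 501)
        mean, sd, cv2 = sv.summarize(v)
        mean_o = sum(v) / len(v)
        var_o = sum((x - mean_o) ** 2 for x in v) / (len(v) - 1)
        assert mean == pytest.approx(mean_o, rel=1e-12)
        assert sd == pytest.approx(var_o ** 0.5, rel=1e-12)
        assert cv2 == pytest.approx(var_o / mean_o ** 2, rel=1e-12)


class TestRelativeEffect:
    @pytest.mark.parametrize(
        "mutant, control, expected",
        [(12.0, 10.0, (0.2, 0.2)), (10.0, 10.0, (0.0, 0.0)), (8.0, 10.0, (-0.2, 0.2))],
    )
    def test_formula(self, mutant, control, expected):
        assert sv.relative_effect(mutant, control) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(InvalidInputError):
            sv.relative_effect(1.0, 0.0)


class TestExpressionSummary:
    def test_toy_grid_hand_values(self):
        grid = pd.DataFrame([[1, 2, 3], [10, 20, 30]],
                            index=pd.Index(["g1", "g2"], name="gene"))
        out = sv.expression_summary(grid).set_index("gene")
        assert out.loc["g1", "cv2_expr"] == pytest.approx(0.25)
        assert out.loc["g2", "cv2_expr"] == pytest.approx(0.25)
        assert out.loc["g1", "log10_mean_expr"] == pytest.approx(np.log10(2))
        assert out.loc["g2", "log10_mean_expr"] == pytest.approx(np.log10(20))

    def test_constant_gene_zero_cv2(self):
        grid = pd.DataFrame([[7.0, 7.0, 7.0]], index=pd.Index(["g"], name="gene"))
        assert sv.expression_summary(grid)["cv2_expr"].iloc[0] == 0.0

    def test_zero_mean_gene_flagged(self):
        grid = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]],
                            index=pd.Index(["dead", "ok"], name="gene"))
        out = sv.expression_summary(grid).set_index("gene")
        assert bool(out.loc["dead", "zero_mean"])
        assert np.isnan(out.loc["dead", "log10_mean_expr"])

    def test_single_sample_rejected(self):
        grid = pd.DataFrame([[1.0]], index=pd.Index(["g"], name="gene"))
        with pytest.raises(InsufficientDataError):
            sv.expression_summary(grid)


class TestPearsonTest:
    def test_perfect_linearity(self):
        x = np.array([0.5, 1.0, 2.0, 3.5, 7.0])
        res = sv.pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res_neg = sv.pearson_test([1, 2, 3], [6, 4, 2])
        assert res_neg.r == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        """x=[1,2,3,4], y=[1,3,2,4]: r = 0.8, p from the t(n-2) formula."""
        res = sv.pearson_test([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        t = 0.8 * np.sqrt((4 - 2) / (1 - 0.8 ** 2))
        assert res.p == pytest.approx(2 * sps.t.sf(t, df=2), rel=1e-9)
        assert res.n == 4

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            sv.pearson_test([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            sv.pearson_test([1, 1, 1], [1, 2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100), b=st.floats(-50, 50),
        c=st.floats(0.01, 100), d=st.floats(-50, 50),
    )
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        ref = sv.pearson_test(x, y)
        moved = sv.pearson_test(a * x + b, c * y + d)
        assert moved.r == pytest.approx(ref.r, rel=1e-9, abs=1e-12)
        assert moved.p == pytest.approx(ref.p, rel=1e-9)


class TestScreenTable:
    def test_sixteen_records_per_parameter(self, screen_table):
        counts = screen_table.groupby("parameter").size()
        assert (counts == 16).all()
        assert set(screen_table["parameter"]) == set(rs.PARAMETERS)

    def test_unmapped_mutant_rejected_with_reason(self, default_bundle):
        _, table, matrix, gene_map, _ = default_bundle
        gm = gene_map[gene_map["genotype"] != "pmr6"]
        em = sv.ExpressionMatrix(values=matrix, gene_map=gm)
        st_, rejects = sv.build_screen_table(table, em)
        assert (st_.groupby("parameter").size() == 15).all()
        assert len(rejects) == 1 and rejects[0]["genotype"] == "pmr6"

    def test_round_trip(self, screen_table, tmp_path):
        path = tmp_path / "screen.csv"
        screen_table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, screen_table.reset_index(drop=True))

    def test_row_order_does_not_change_screens(self, screen_table):
        shuffled = screen_table.sample(frac=1.0, random_state=5)
        a = sv.run_screens(screen_table)
        b = sv.run_screens(shuffled)
        np.testing.assert_allclose([[r.r, r.p] for r in a],
                                   [[r.r, r.p] for r in b], rtol=1e-9)


class TestRunScreens:
    def test_full_grid(self, screen_table):
        results = sv.run_screens(screen_table)
        assert len(results) == 16  # 4 parameters x 2 responses x 2 covariates
        keys = {(r.response, r.covariate) for r in results}
        assert len(keys) == 16

    def test_planted_slope_detected(self, screen_table):
        """Default conditions plant a positive area-CV^2 vs log-expression
        slope; the corresponding screen must find r > 0, p < 0.05."""
        res = {(r.response, r.covariate): r for r in sv.run_screens(screen_table)}
        hit = res[("cv2(area)", "log10_mean_expr")]
        assert hit.r > 0 and hit.p < 0.05

    def test_log_base_cannot_change_results(self, screen_table):
        """Replacing log10 by ln in the covariate is an affine map, so every
        screen's r and p are unchanged."""
        natural = screen_table.copy()
        natural["log10_mean_expr"] = natural["log10_mean_expr"] * np.log(10.0)
        a = sv.run_screens(screen_table)
        b = sv.run_screens(natural)
        for ra, rb in zip(a, b):
            assert rb.r == pytest.approx(ra.r, rel=1e-12)
            assert rb.p == pytest.approx(ra.p, rel=1e-12)


class TestReferenceBand:
    @staticmethod
    def _table_from_batch_cv2(cv2_by_batch):
        rows = []
        for batch, cv2 in cv2_by_batch.items():
            # [1-d, 1, 1+d] has mean 1 and sample sd d, hence CV^2 = d^2
            d = np.sqrt(cv2)
            for i, v in enumerate([1 - d, 1.0, 1 + d]):
                rows.append({"genotype": "col-0", "batch": batch, "sepal_id": f"{batch}-{i}",
                             "length": v, "width": v, "area": v, "aspect_ratio": v})
        return pd.DataFrame(rows)

    def test_hand_computed_band(self):
        table = self._table_from_batch_cv2({"b1": 0.01, "b2": 0.03})
        band = {b.parameter: b for b in sv.reference_band(table)}["area"]
        assert band.mean_cv2 == pytest.approx(0.02, rel=1e-9)
        assert band.sd_cv2 == pytest.approx(np.sqrt(2) * 0.01, rel=1e-9)

    def test_identical_batches_zero_sd(self):
        table = self._table_from_batch_cv2({"b1": 0.02, "b2": 0.02, "b3": 0.02})
        for band in sv.reference_band(table):
            assert band.sd_cv2 == pytest.approx(0.0, abs=1e-12)

    def test_single_batch_rejected(self):
        table = self._table_from_batch_cv2({"b1": 0.01})
        with pytest.raises(InsufficientDataError):
            sv.reference_band(table)

    def test_band_brackets_effect_free_mutants_about_68_percent(self):
        """With no planted effect, the 1-sd wild-type band should contain a
        mutant's estimated CV^2 in roughly 68% of cases."""
        inside = total = 0
        for s in range(40):
            cfg = sv.SimConfig(planted_slope=0.0, effect_scale=0.0, noise_sd=0.0,
                               n_expr_genes=16, seed=1000 + s)
            table, _ = sv.gen_measurement_table(cfg)
            band = {b.parameter: b for b in sv.reference_band(table)}["area"]
            stats = sv.summary_table(table)
            mut = stats[(stats["genotype"] != "col-0") & (stats["parameter"] == "area")]
            inside += ((mut["cv2"] > band.mean_cv2 - band.sd_cv2)
                       & (mut["cv2"] < band.mean_cv2 + band.sd_cv2)).sum()
            total += len(mut)
        assert 0.55 <= inside / total <= 0.80


class TestSampleSizeConfound:
    def test_equal_sample_sizes_undefined(self, screen_table):
        st_ = screen_table.copy()
        st_["n"] = 60
        with pytest.raises(UndefinedCorrelationError):
            sv.sample_size_confound(st_)

    def test_affine_transform_of_n_leaves_r_unchanged(self, screen_table):
        doubled = screen_table.copy()
        doubled["n"] = 2 * doubled["n"]
        a = sv.sample_size_confound(screen_table)
        b = sv.sample_size_confound(doubled)
        for ra, rb in zip(a, b):
            assert rb.r == pytest.approx(ra.r, rel=1e-12)
            assert rb.p == pytest.approx(ra.p, rel=1e-12)
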