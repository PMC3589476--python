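"""Elementary statistics and the selection cascade, checked against
independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirscreen.io import ExpressionMatrix, SampleSheet
from mirscreen.screening import (
    ScreeningConfig,
    apply_cascade,
    cohort_comparability,
    de_screen,
    fisher_exact_2x2,
    fold_change,
    t_from_summary,
    two_sample_t,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def t_sf_numeric(t_abs: float, df: float) -> float:
    """Two-sided t-test p-value by numerical integration of the t density."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    grid = np.linspace(t_abs, t_abs + 60.0, 400_001)
    dens = const * (1 + grid**2 / df) ** (-(df + 1) / 2)
    return float(2 * np.trapezoid(dens, grid))


def pooled_t_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def permutation_p(x, y, stat=None):
    """Exact two-sided permutation p over all group splits.

    ``stat`` maps (x, y) to a non-negative extremity score; the default is
    the absolute mean difference.
    """
    if stat is None:
        stat = lambda u, v: abs(np.mean(u) - np.mean(v))
    pooled = np.asarray(list(x) + list(y), float)
    n1 = len(x)
    observed = stat(np.asarray(x, float), np.asarray(y, float))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        count += stat(pooled[sel], pooled[~sel]) >= observed - 1e-12
        total += 1
    return count / total


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point_prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    observed = point_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point_prob(k) for k in range(lo, hi + 1)
               if point_prob(k) <= observed * (1 + 1e-9))


def cascade_by_hand(rows, cfg):
    """Independent re-evaluation of the three cascade rules, row by row."""
    de, norm, final = [], [], []
    for r in rows:
        if not (r["p_case"] < cfg.alpha_de and r["fc_computable"]
                and r["fc_ratio"] >= cfg.fc_min):
            continue
        de.append(r["mirna"])
        if not r["p_post"] > cfg.alpha_norm:
            continue
        norm.append(r["mirna"])
        if r["p_other"] < cfg.alpha_spec and r["other_direction"] == r["direction"]:
            continue
        final.append(r["mirna"])
    return de, norm, final


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------


class TestTwoSampleT:
    def test_identical_multisets(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_pooled_matches_hand_formula_and_numeric_integration(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        t, df, p = two_sample_t(x, y, variant="pooled")
        t_hand, df_hand = pooled_t_by_hand(x, y)
        assert df == df_hand == 6
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(t_sf_numeric(abs(t_hand), 6), rel=1e-6)

    def test_orders_permutations_like_mean_difference(self):
        """For a fixed pooled sample, |t| must rank all group splits exactly
        as |mean difference| does (the pooled t is a monotone transform of it
        given fixed total sum of squares), so the exact permutation p is the
        same under either statistic."""
        rng = np.random.default_rng(3)
        for _ in range(4):
            x, y = rng.normal(0.7, 1, 3), rng.normal(0, 1, 5)
            by_mean = permutation_p(x, y)
            by_t = permutation_p(x, y, stat=lambda u, v: abs(two_sample_t(u, v)[0]))
            assert by_t == by_mean

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means_convention(self):
        t, _, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([2.0, 2.0], [3.0, 3.0])

    def test_welch_uses_satterthwaite_df(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 50.0]
        _, df, _ = two_sample_t(x, y, variant="welch")
        assert df < len(x) + len(y) - 2  # strictly below the pooled df here


class TestTFromSummary:
    def test_equal_means_give_p_one(self):
        _, _, p = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert p == 1.0

    def test_matches_two_sample_t_on_moment_matched_vectors(self):
        # the study population's age row: 54.9 (9.1) vs 53.7 (9.9), n=20/20
        rng = np.random.default_rng(8)

        def with_moments(mean, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        x = with_moments(54.9, 9.1, 20)
        y = with_moments(53.7, 9.9, 20)
        t_raw, df_raw, p_raw = two_sample_t(x, y)
        t_sum, df_sum, p_sum = t_from_summary(54.9, 9.1, 20, 53.7, 9.9, 20)
        assert t_sum == pytest.approx(t_raw, rel=1e-9)
        assert df_sum == df_raw
        assert p_sum == pytest.approx(p_raw, rel=1e-9)

    def test_doubling_both_sds_halves_t(self):
        t1, _, _ = t_from_summary(10.0, 2.0, 15, 8.0, 3.0, 15)
        t2, _, _ = t_from_summary(10.0, 4.0, 15, 8.0, 6.0, 15)
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)


class TestFisherExact:
    def test_race_counts_example(self):
        p = fisher_exact_2x2(4, 16, 2, 18)
        assert round(p, 2) == 0.66
        assert p == pytest.approx(fisher_two_sided_enumeration(4, 16, 2, 18), abs=1e-9)

    def test_degenerate_column_gives_p_one(self):
        assert fisher_exact_2x2(0, 7, 0, 9) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), abs=1e-9
        )


class TestFoldChange:
    def test_reported_group_means_example(self):
        fc = fold_change(2248.4, 606.7)
        assert fc.direction == "up"
        assert fc.fc_ratio == pytest.approx(3.71, abs=0.005)
        assert fc.log2_fc == pytest.approx(math.log2(2248.4 / 606.7))

    def test_equal_means(self):
        fc = fold_change(5.0, 5.0)
        assert fc.fc_ratio == 1.0 and fc.log2_fc == 0.0

    def test_nonpositive_mean_flagged_not_computable(self):
        fc = fold_change(-5.0, 10.0)
        assert not fc.computable
        assert math.isnan(fc.fc_ratio) and math.isnan(fc.log2_fc)
        assert fc.direction == "down"

    def test_ratio_is_symmetric_and_log_fc_signed(self):
        up, down = fold_change(40.0, 10.0), fold_change(10.0, 40.0)
        assert up.fc_ratio == down.fc_ratio == 4.0
        assert up.log2_fc == -down.log2_fc == 2.0


# ---------------------------------------------------------------------------
# DE screen
# ---------------------------------------------------------------------------


def screen_matrix(values, sheet):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        data=pd.DataFrame(
            values,
            index=[f"p{i}" for i in range(values.shape[0])],
            columns=sheet.sample_ids,
        ),
        stage="normalized",
    )


class TestDeScreen:
    def test_planted_upshift_found(self, four_cohort_sheet):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 5, size=(1, 12))
        planted = base.copy()
        planted[0, 3:6] *= 4  # bc_pre samples
        m = screen_matrix(planted, four_cohort_sheet)
        res = de_screen(m, four_cohort_sheet)
        row = res.iloc[0]
        assert row.direction == "up"
        assert row.p_case < 0.05
        assert row.fc_ratio > 2

    def test_within_cohort_label_permutation_invariance(self, four_cohort_sheet):
        rng = np.random.default_rng(1)
        m = screen_matrix(rng.normal(100, 20, (6, 12)), four_cohort_sheet)
        res1 = de_screen(m, four_cohort_sheet)
        # swap the two control samples' columns: same cohort, same multiset
        permuted = m.data[["s2", "s1", "s3"] + [f"s{i}" for i in range(4, 13)]]
        permuted.columns = m.sample_ids
        res2 = de_screen(
            ExpressionMatrix(data=permuted, stage="normalized"), four_cohort_sheet
        )
        pd.testing.assert_frame_equal(res1, res2)

    def test_missing_cohort_named_in_error(self):
        rows = [{"sample_id": f"s{i}", "cohort": "control"} for i in range(3)]
        rows += [{"sample_id": f"t{i}", "cohort": "bc_pre"} for i in range(3)]
        rows += [{"sample_id": f"u{i}", "cohort": "bc_post"} for i in range(3)]
        sheet = SampleSheet(frame=pd.DataFrame(rows))
        m = screen_matrix(np.ones((2, 9)), sheet)
        with pytest.raises(ValueError, match="other_cancer"):
            de_screen(m, sheet)

    def test_all_contrast_pvalues_populated(self, four_cohort_sheet):
        rng = np.random.default_rng(2)
        m = screen_matrix(rng.uniform(10, 500, (8, 12)), four_cohort_sheet)
        res = de_screen(m, four_cohort_sheet)
        for col in ("p_case", "p_post", "p_other"):
            assert res[col].between(0, 1).all()
        assert len(res) == 8


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def random_contrast_rows(rng, n):
    rows = []
    for i in range(n):
        mean_control = rng.uniform(-10, 500)
        mean_pre = rng.uniform(-10, 500)
        fc_ok = mean_control > 0 and mean_pre > 0
        ratio = (
            max(mean_pre, mean_control) / min(mean_pre, mean_control)
            if fc_ok
            else float("nan")
        )
        rows.append(
            {
                "mirna": f"m{i}",
                "mean_control": mean_control,
                "mean_bc_pre": mean_pre,
                "mean_bc_post": rng.uniform(0, 500),
                "mean_other": rng.uniform(0, 500),
                "direction": "up" if mean_pre > mean_control else "down",
                "fc_ratio": ratio,
                "log2_fc": float("nan"),
                "fc_computable": fc_ok,
                "p_case": rng.uniform(0, 0.2),
                "p_post": rng.uniform(0, 0.5),
                "p_other": rng.uniform(0, 0.5),
                "other_direction": rng.choice(["up", "down"]),
            }
        )
    return rows


class TestApplyCascade:
    def test_empty_input(self):
        report = apply_cascade(pd.DataFrame())
        assert report.n_analyzed == report.n_de == report.n_normalizing == 0
        assert report.final_candidates == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_contrast_rows(rng, 60)
        cfg = ScreeningConfig()
        report = apply_cascade(pd.DataFrame(rows), cfg)
        de, norm, final = cascade_by_hand(rows, cfg)
        assert report.de_candidates == de
        assert report.normalizing_candidates == norm
        assert report.final_candidates == final
        assert report.n_nonspecific == len(norm) - len(final)

    def test_pure_function_rerun_identical(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(random_contrast_rows(rng, 40))
        r1, r2 = apply_cascade(frame), apply_cascade(frame)
        assert r1.to_dict() == r2.to_dict()

    @given(st.integers(0, 2**31 - 1), st.floats(0.005, 0.05), st.floats(2.0, 6.0))
    @settings(max_examples=40, deadline=None)
    def test_tightening_thresholds_never_enlarges_final_set(self, seed, alpha, fc_min):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(random_contrast_rows(rng, 40))
        loose = apply_cascade(frame, ScreeningConfig())
        tight = apply_cascade(frame, ScreeningConfig(alpha_de=alpha, fc_min=fc_min))
        assert set(tight.final_candidates) <= set(loose.final_candidates)

    def test_opposite_direction_significance_does_not_disqualify(self):
        row = {
            "mirna": "m", "mean_control": 100.0, "mean_bc_pre": 300.0,
            "mean_bc_post": 110.0, "mean_other": 20.0, "direction": "up",
            "fc_ratio": 3.0, "log2_fc": math.log2(3), "fc_computable": True,
            "p_case": 0.01, "p_post": 0.5, "p_other": 0.001,
            "other_direction": "down",
        }
        report = apply_cascade(pd.DataFrame([row]))
        assert report.final_candidates == ["m"]


class TestCohortComparability:
    def test_age_and_race_tests(self):
        from mirscreen.datasets import load_cohort_demographics

        out = cohort_comparability(load_cohort_demographics())
        # summary t on the printed moments; Fisher on the race counts
        assert out["age_df"] == 38
        assert out["age_p"] == pytest.approx(
            t_sf_numeric(abs(out["age_t"]), 38), rel=1e-5
        )
        assert round(out["race_p"], 2) == 0.66
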