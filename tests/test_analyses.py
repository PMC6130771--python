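import numpy as np
import pandas as pd
import pytest

import devotei as d
from _oracles import mannwhitney_exact_oracle, spearman_oracle, tau_oracle


def _matrix(values, columns=None, scale="normalized_linear"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    cols = columns or [f"s{j}" for j in range(arr.shape[1])]
    return d.ExpressionMatrix(
        data=pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols),
        scale=scale,
    )


class TestDeltaEm:
    def test_hand_value(self):
        tl = d.StageTimeline(["a", "b", "c"], ["early", "early", "middle"])
        tei = pd.Series({"a": 2.0, "b": 4.0, "c": 1.0})
        assert d.delta_em(tei, tl) == pytest.approx(2.0)  # mean(2,4) - 1

    def test_symmetry_gives_zero(self):
        tl = d.StageTimeline(["a", "b"], ["early", "middle"])
        tei = pd.Series({"a": 3.3, "b": 3.3})
        assert d.delta_em(tei, tl) == 0.0

    def test_premzt_and_late_are_ignored(self, simple_timeline):
        tei = pd.Series({"s0": 100.0, "s1": 2.0, "s2": 4.0, "s3": 1.0, "s4": -50.0})
        assert d.delta_em(tei, simple_timeline) == pytest.approx(2.0)

    def test_missing_stage_rejected(self, simple_timeline):
        tei = pd.Series({"s1": 1.0, "s2": 2.0})  # middle stage s3 absent
        with pytest.raises(ValueError, match="middle"):
            d.delta_em(tei, simple_timeline)


class TestPermutationTest:
    def test_constant_parameter_is_degenerate_with_p_one(self, small_matrix, simple_timeline):
        param = pd.Series(2.0, index=small_matrix.gene_ids, name="omega0")
        res = d.permutation_test(small_matrix, param, simple_timeline, n_perm=200, seed=0)
        assert res.degenerate
        assert res.p_normal == 1.0 and res.p_empirical == 1.0
        assert res.delta_observed == pytest.approx(0.0)

    def test_deterministic_under_fixed_seed(self, small_matrix, simple_timeline):
        param = pd.Series(
            np.random.default_rng(1).gamma(2, 0.1, 20),
            index=small_matrix.gene_ids,
            name="omega0",
        )
        a = d.permutation_test(small_matrix, param, simple_timeline, n_perm=500, seed=7)
        b = d.permutation_test(small_matrix, param, simple_timeline, n_perm=500, seed=7)
        assert a == b

    def test_empirical_p_never_zero_and_directions_are_complementary(
        self, small_matrix, simple_timeline
    ):
        param = pd.Series(
            np.random.default_rng(2).gamma(2, 0.1, 20),
            index=small_matrix.gene_ids,
            name="omega0",
        )
        lo = d.permutation_test(
            small_matrix, param, simple_timeline, "middle_lower", n_perm=500, seed=3
        )
        hi = d.permutation_test(
            small_matrix, param, simple_timeline, "middle_higher", n_perm=500, seed=3
        )
        assert 0 < lo.p_empirical <= 1 and 0 < hi.p_empirical <= 1
        assert lo.p_normal + hi.p_normal == pytest.approx(1.0)

    def test_small_n_perm_warns(self, small_matrix, simple_timeline):
        param = pd.Series(
            np.random.default_rng(3).gamma(2, 0.1, 20),
            index=small_matrix.gene_ids,
        )
        with pytest.warns(UserWarning, match="n_perm"):
            d.permutation_test(small_matrix, param, simple_timeline, n_perm=99, seed=0)

    def test_invalid_direction_rejected(self, small_matrix, simple_timeline):
        param = pd.Series(1.0, index=small_matrix.gene_ids)
        with pytest.raises(ValueError, match="direction"):
            d.permutation_test(small_matrix, param, simple_timeline, direction="sideways")


class TestPleiotropy:
    def _calls(self, rows, stages=None):
        arr = np.asarray(rows, dtype=bool)
        cols = stages or [f"s{j}" for j in range(arr.shape[1])]
        return d.ExpressionCallMatrix(
            calls=pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols),
            rule="test",
        )

    def test_breadth_comparison_is_strict(self):
        calls = self._calls(
            [
                [1, 1, 1, 0, 0],   # 3/5 = 0.6 > 0.5 → flagged
                [1, 1, 0, 0, 0],   # 0.4 → not
            ]
        )
        flags = d.pleiotropy_flags(calls, 0.5)
        assert flags.tolist() == [True, False]
        half = self._calls([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]])
        assert not d.pleiotropy_flags(half, 0.5).iloc[0]  # exactly 50% not flagged

    @pytest.mark.parametrize("n_on, expected", [(7, False), (8, True)])
    def test_seventy_percent_threshold_boundary(self, n_on, expected):
        row = [1] * n_on + [0] * (10 - n_on)
        flags = d.pleiotropy_flags(self._calls([row]), 0.7)
        assert bool(flags.iloc[0]) is expected

    def test_raising_threshold_never_adds_flags(self):
        rng = np.random.default_rng(0)
        calls = self._calls(rng.random((50, 8)) < 0.6)
        prev = d.pleiotropy_flags(calls, 0.3)
        for t in (0.5, 0.7, 0.9):
            cur = d.pleiotropy_flags(calls, t)
            assert not (cur & ~prev).any()
            prev = cur

    def test_premzt_exclusion_changes_denominator(self, simple_timeline):
        # expressed only at the preMZT stage + one early stage: breadth 2/5
        # with preMZT counted, 1/4 with it excluded
        calls = self._calls([[1, 1, 0, 0, 0]], stages=simple_timeline.stage_ids)
        incl = d.pleiotropy_flags(calls, 0.3)
        excl = d.pleiotropy_flags(calls, 0.3, timeline=simple_timeline, exclude_premzt=True)
        assert incl.iloc[0] and not excl.iloc[0]

    def test_chi_square_hand_value_equal_expressed_totals(self):
        # equal expressed totals (30, 30) with pleiotropic counts (10, 20):
        # expected counts (15, 15), chi2 = 25/15 + 25/15 = 10/3
        rows = np.zeros((50, 2), dtype=bool)
        rows[:10] = True            # flagged, expressed at both stages
        rows[10:20, 1] = True       # flagged, stage 2 only
        rows[20:40, 0] = True       # unflagged, stage 1 only
        rows[40:, 1] = True         # unflagged, stage 2 only
        calls = self._calls(rows)
        flags = pd.Series([True] * 20 + [False] * 30, index=calls.gene_ids)
        res = d.pleiotropy_profile(calls, flags)
        assert res.table["n_expressed"].tolist() == [30, 30]
        assert res.table["n_pleiotropic"].tolist() == [10, 20]
        assert res.chi2_statistic == pytest.approx(10 / 3)

    def test_chi_square_equal_proportions_gives_zero(self):
        calls = self._calls(np.ones((30, 3)))
        flags = pd.Series([True] * 10 + [False] * 20, index=calls.gene_ids)
        result = d.pleiotropy_profile(calls, flags)
        assert result.chi2_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 2

    def test_equal_totals_hand_chi_square(self):
        # equal expressed totals (30 each), pleiotropic counts 10 and 20
        rows = np.ones((30, 2), dtype=bool)
        calls = self._calls(rows)
        flags = pd.Series(False, index=calls.gene_ids)
        # a gene flagged pleiotropic counts at every stage it is expressed in;
        # emulate unequal counts by flagging 10 genes and marking 10 others
        # expressed only at stage 2 and flagged
        rows = np.ones((40, 2), dtype=bool)
        rows[30:, 0] = False
        calls = self._calls(rows)
        flags = pd.Series(False, index=calls.gene_ids)
        flags.iloc[:10] = True
        flags.iloc[30:] = True
        res = d.pleiotropy_profile(calls, flags)
        assert res.table["n_pleiotropic"].tolist() == [10, 20]
        exp1 = 30 * 30 / 70
        exp2 = 30 * 40 / 70
        hand = (10 - exp1) ** 2 / exp1 + (20 - exp2) ** 2 / exp2
        assert res.chi2_statistic == pytest.approx(hand)

    def test_single_stage_rejected(self):
        calls = self._calls(np.ones((5, 1)))
        flags = pd.Series(True, index=calls.gene_ids)
        with pytest.raises(ValueError, match="at least 2 stages"):
            d.pleiotropy_profile(calls, flags)

    def test_stage_without_expressed_genes_rejected(self):
        calls = self._calls([[1, 0], [1, 0]])
        flags = pd.Series(False, index=calls.gene_ids)
        with pytest.raises(ValueError, match="zero expressed"):
            d.pleiotropy_profile(calls, flags)


class TestWilcoxonComparison:
    def test_identical_groups_give_p_near_one(self):
        param = pd.Series(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef")
        )
        groups = pd.Series([True, True, True, False, False, False], index=list("abcdef"))
        _, p = d.compare_param_by_group(param, groups)
        assert p > 0.9

    def test_fully_separated_small_groups_match_exact_enumeration(self):
        param = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"), dtype=float)
        groups = pd.Series([True, True, True, False, False, False], index=list("abcdef"))
        u, p = d.compare_param_by_group(param, groups)
        u_oracle, p_oracle = mannwhitney_exact_oracle([1, 2, 3], [10, 11, 12])
        assert u == pytest.approx(u_oracle)  # U = 0
        assert p == pytest.approx(p_oracle)  # 2/20 = 0.1

    def test_random_tie_free_small_samples_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.permutation(20)[:6].astype(float)
            b = (rng.permutation(20)[:8] + 100).astype(float) * rng.choice([1, 0.01])
            values = np.concatenate([a, b])
            if len(np.unique(values)) < len(values):
                continue
            param = pd.Series(values, index=[f"g{i}" for i in range(14)])
            groups = pd.Series([True] * 6 + [False] * 8, index=param.index)
            u, p = d.compare_param_by_group(param, groups)
            u_o, p_o = mannwhitney_exact_oracle(list(a), list(b))
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_empty_group_rejected(self):
        param = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series([True, True], index=["a", "b"])
        with pytest.raises(ValueError, match="nonempty"):
            d.compare_param_by_group(param, groups)


class TestTau:
    def _panel(self, rows, tissues=("brain", "liver", "testis")):
        arr = np.atleast_2d(np.asarray(rows, dtype=float))
        return d.TissuePanel(
            data=pd.DataFrame(
                arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=list(tissues)
            ),
            testis="testis",
        )

    @pytest.mark.parametrize(
        "row, expected",
        [([8, 8, 8], 0.0), ([0, 0, 5], 1.0), ([2, 4, 8], 0.625)],
    )
    def test_hand_values(self, row, expected):
        out = d.tau(self._panel([row]))
        assert out["tau"].iloc[0] == pytest.approx(expected)
        assert out["tau"].iloc[0] == pytest.approx(tau_oracle(row))

    def test_scale_invariance_and_tissue_permutation(self):
        rng = np.random.default_rng(8)
        rows = rng.lognormal(1, 1, size=(30, 3))
        base = d.tau(self._panel(rows))
        scaled = d.tau(self._panel(rows * 3.7))
        np.testing.assert_allclose(scaled["tau"], base["tau"], rtol=1e-12)
        permuted = d.tau(self._panel(rows[:, [2, 0, 1]], tissues=("testis", "brain", "liver")))
        np.testing.assert_allclose(permuted["tau"], base["tau"], rtol=1e-12)

    def test_negative_log_values_floored_and_silent_genes_removed(self):
        out = d.tau(self._panel([[-2.0, -1.0, 4.0], [0.0, 0.0, 0.0]]))
        assert list(out.index) == ["g0"]
        assert out["tau"].iloc[0] == pytest.approx(1.0)

    def test_testis_specific_needs_top_tissue_and_tau(self):
        out = d.tau(self._panel([[0, 0, 9], [9, 0, 0], [5, 4.5, 6]]))
        assert out["is_testis_specific"].tolist() == [True, False, False]

    def test_single_tissue_panel_rejected(self):
        with pytest.raises(ValueError, match="2 tissues"):
            d.TissuePanel(
                data=pd.DataFrame({"testis": [1.0]}, index=["g0"]), testis="testis"
            )


class TestRetrogeneTrend:
    def _setup(self, medians_target):
        # one retrogene whose profile is exactly the target medians
        data = pd.DataFrame(
            [medians_target, [1] * len(medians_target)],
            index=["retro", "other"],
            columns=[f"s{j}" for j in range(len(medians_target))],
            dtype=float,
        )
        m = d.ExpressionMatrix(data, "normalized_linear")
        flags = pd.Series([True, False], index=["retro", "other"])
        return m, flags

    def test_monotone_profiles_give_extreme_rho(self):
        m, flags = self._setup([1, 2, 3, 4, 5])
        medians, rho, p = d.retrogene_trend(m, flags)
        assert rho == pytest.approx(1.0)
        m2, flags2 = self._setup([5, 4, 3, 2, 1])
        _, rho2, _ = d.retrogene_trend(m2, flags2)
        assert rho2 == pytest.approx(-1.0)

    def test_rho_matches_rank_formula_oracle(self):
        m, flags = self._setup([1, 3, 2, 4, 5])
        medians, rho, p = d.retrogene_trend(m, flags)
        assert rho == pytest.approx(0.9)
        assert rho == pytest.approx(spearman_oracle([1, 2, 3, 4, 5], [1, 3, 2, 4, 5]))

    def test_exact_permutation_p_below_five_stages(self):
        m, flags = self._setup([1, 2, 4, 3])
        _, rho, p = d.retrogene_trend(m, flags)
        # 4 stages: exact p over 4! = 24 orderings; |rho|=0.8 is matched or
        # beaten by 8 of them
        assert p == pytest.approx(8 / 24)

    def test_testis_exclusion_can_remove_all_retrogenes(self):
        m, flags = self._setup([1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="no retrogenes"):
            d.retrogene_trend(m, flags, exclude={"retro"})

    def test_needs_three_stages(self):
        data = pd.DataFrame([[1.0, 2.0]], index=["retro"], columns=["s0", "s1"])
        m = d.ExpressionMatrix(data, "normalized_linear")
        with pytest.raises(ValueError, match="3 stages"):
            d.retrogene_trend(m, pd.Series([True], index=["retro"]))


class TestConnectivityDuplicability:
    def test_identity_relation_gives_rho_one(self):
        ann = pd.DataFrame(
            {"connectivity": np.arange(20), "paralog_count": np.arange(20)},
            index=[f"g{i}" for i in range(20)],
        )
        rho, p, table, undefined = d.connectivity_duplicability(ann)
        assert not undefined
        assert rho == pytest.approx(1.0)
        assert table["paralog_mean"].is_monotonic_increasing

    def test_independent_variables_give_near_zero_rho(self):
        rng = np.random.default_rng(12)
        ann = pd.DataFrame(
            {
                "connectivity": rng.poisson(20, 1000),
                "paralog_count": rng.poisson(3, 1000),
            },
            index=[f"g{i}" for i in range(1000)],
        )
        rho, p, table, undefined = d.connectivity_duplicability(ann)
        assert abs(rho) < 0.1

    def test_all_tied_connectivity_flagged_undefined(self):
        ann = pd.DataFrame(
            {"connectivity": [3] * 12, "paralog_count": range(12)},
            index=[f"g{i}" for i in range(12)],
        )
        rho, p, table, undefined = d.connectivity_duplicability(ann)
        assert undefined and np.isnan(rho)

    def test_too_few_genes_rejected(self):
        ann = pd.DataFrame(
            {"connectivity": range(5), "paralog_count": range(5)},
            index=[f"g{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="at least 10"):
            d.connectivity_duplicability(ann)
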