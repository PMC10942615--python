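"""State differences, pooled sd, global threshold and hybrid flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import hdxtherm as ht
from hdxtherm.differential import HybridParams, write_residual_csv

# t quantiles frozen from an independent statistics environment (R qt).
R_T975 = {4: 2.77644510519779, 10: 2.22813885198627,
          100: 1.98397151852355, 1800: 1.96128278458128}


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "sequence", "state",
                 "timepoint_s", "replicate", "uptake_da"],
    )


def _cell(start, end, seq, state, t, values):
    return [("p", start, end, seq, state, t, i + 1, v)
            for i, v in enumerate(values)]


class TestSummarizeCells:
    def test_hand_computed_mean_sd(self):
        table = _table(_cell(1, 5, "ACDEF", "free", 30.0, [1.0, 1.2, 1.1]))
        cells = ht.summarize_cells(table)
        assert len(cells) == 1
        assert cells.loc[0, "mean"] == pytest.approx(1.1)
        assert cells.loc[0, "sd"] == pytest.approx(0.1)
        assert cells.loc[0, "n"] == 3

    def test_identical_replicates_zero_sd(self):
        cells = ht.summarize_cells(
            _table(_cell(1, 5, "ACDEF", "free", 30.0, [2.0, 2.0, 2.0]))
        )
        assert cells.loc[0, "sd"] == 0.0

    def test_single_replicate_excluded(self, caplog):
        rows = _cell(1, 5, "ACDEF", "free", 30.0, [1.0, 1.1]) + _cell(
            6, 9, "GHIK", "free", 30.0, [2.0]
        )
        with caplog.at_level("WARNING"):
            cells = ht.summarize_cells(_table(rows))
        assert len(cells) == 1
        assert "n=1" in caplog.text


class TestPooledSd:
    def test_hand_value_two_cells(self):
        cells = pd.DataFrame({"sd": [0.1, 0.3], "n": [3, 3]})
        s, df = ht.pooled_sd(cells)
        assert s == pytest.approx(np.sqrt((0.01 + 0.09) / 2))
        assert df == 4

    def test_constant_sd_is_fixed_point(self):
        cells = pd.DataFrame({"sd": [0.2] * 10, "n": [3] * 10})
        s, _ = ht.pooled_sd(cells)
        assert s == pytest.approx(0.2)

    def test_zero_noise_gives_zero(self):
        cells = pd.DataFrame({"sd": [0.0] * 4, "n": [3] * 4})
        assert ht.pooled_sd(cells)[0] == 0.0


class TestGlobalThreshold:
    def test_zero_sd_gives_zero(self):
        assert ht.global_threshold(0.0, 4, 3, 3) == 0.0

    @pytest.mark.parametrize("df", sorted(R_T975))
    def test_matches_independent_t_quantiles(self, df):
        got = ht.global_threshold(0.1, df, 3, 3, 0.05)
        expected = R_T975[df] * 0.1 * np.sqrt(2.0 / 3.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_normal_limit(self):
        got = ht.global_threshold(1.0, 1e9, 3, 3, 0.05)
        assert got == pytest.approx(1.959964 * np.sqrt(2 / 3), abs=1e-4)

    @given(scale=st.floats(0.01, 10.0))
    def test_homogeneous_degree_one_in_sd(self, scale):
        base = ht.global_threshold(0.1, 4, 3, 3)
        assert ht.global_threshold(0.1 * scale, 4, 3, 3) == pytest.approx(
            base * scale, rel=1e-12
        )


class TestWelch:
    def test_identical_groups(self):
        t, _, p = ht.welch_ttest([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_frozen_reference_values(self):
        # frozen from R t.test (Welch)
        t, df, p = ht.welch_ttest([1.0, 1.1, 0.9], [0.5, 0.6, 0.4])
        assert t == pytest.approx(6.12372435695795, abs=1e-10)
        assert df == pytest.approx(4.0, abs=1e-10)
        assert p == pytest.approx(0.003602232609104, abs=1e-12)
        t2, df2, p2 = ht.welch_ttest(
            [0.12, 0.55, 0.33, 0.91], [0.47, 0.21, 0.80]
        )
        assert t2 == pytest.approx(-0.0659527439760063, abs=1e-10)
        assert df2 == pytest.approx(4.77766886113713, abs=1e-9)
        assert p2 == pytest.approx(0.950085658380455, abs=1e-12)

    def test_group_swap_negates_t_keeps_p(self):
        a, b = [1.0, 1.2, 0.8], [0.2, 0.4, 0.3]
        t1, _, p1 = ht.welch_ttest(a, b)
        t2, _, p2 = ht.welch_ttest(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_zero_variance(self):
        t, _, p = ht.welch_ttest([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = ht.welch_ttest([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ht.welch_ttest([1.0], [1.0, 2.0])


class TestDeltaUptake:
    def _two_state(self, free_vals, bound_vals):
        rows = []
        for t in (30.0, 300.0, 3000.0):
            rows += _cell(1, 5, "ACDEF", "free", t, free_vals)
        free = _table(rows)
        rows = []
        for t in (30.0, 300.0, 3000.0):
            rows += _cell(1, 5, "ACDEF", "bound", t, bound_vals)
        return free, _table(rows)

    def test_sign_convention_protection_negative(self):
        free, bound = self._two_state([1.0, 1.2, 1.1], [0.5, 0.6, 0.55])
        deltas = ht.delta_uptake(free, bound)
        assert (deltas["delta"] == pytest.approx(-0.55)) is not False
        assert deltas["delta"].iloc[0] == pytest.approx(-0.55)

    def test_identical_states_zero_delta(self):
        free, bound = self._two_state([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        deltas = ht.delta_uptake(free, bound)
        assert np.allclose(deltas["delta"], 0.0)

    def test_sum_delta_over_timepoints(self):
        free, bound = self._two_state([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        deltas = ht.delta_uptake(free, bound)
        assert np.allclose(deltas["sum_delta"], -1.5)

    def test_unmatched_cells_excluded(self, caplog):
        free, bound = self._two_state([1.0, 1.1, 0.9], [0.5, 0.6, 0.4])
        extra = _table(_cell(7, 9, "HIK", "free", 30.0, [1.0, 1.0, 1.0]))
        with caplog.at_level("WARNING"):
            deltas = ht.delta_uptake(pd.concat([free, extra]), bound)
        assert len(deltas) == 3
        assert "unmatched" in caplog.text


class TestHybridSignificance:
    @pytest.mark.parametrize(
        ("delta", "p", "expect_sig", "expect_dir"),
        [
            (-0.50, 0.01, True, "protected"),
            (-0.20, 0.001, False, "none"),  # magnitude fails
            (0.40, 0.30, False, "none"),  # p fails
            (0.40, 0.01, True, "deprotected"),
            (-0.3184, 0.05, True, "protected"),  # boundaries inclusive
        ],
    )
    def test_published_style_rule(self, delta, p, expect_sig, expect_dir):
        deltas = pd.DataFrame(
            {"delta": [delta], "welch_p": [p]}
        )
        params = HybridParams(
            s_pooled=0.1, df_pooled=4, alpha_global=0.05, alpha_ttest=0.05,
            threshold=0.3184,
        )
        out = ht.hybrid_significance(deltas, params)
        assert bool(out.loc[0, "significant"]) is expect_sig
        assert out.loc[0, "direction"] == expect_dir

    def test_flags_invariant_to_peptide_relabeling(self, study_run):
        free, bound = study_run["free"], study_run["bound"]
        deltas1, _ = ht.differential_analysis(free, bound)
        # relabel: shift every peptide by renaming protein ids (order change)
        free2 = free.sort_values(
            ["timepoint_s", "start"], kind="stable"
        ).reset_index(drop=True)
        bound2 = bound.sort_values(
            ["timepoint_s", "start"], kind="stable"
        ).reset_index(drop=True)
        deltas2, _ = ht.differential_analysis(free2, bound2)
        key = ["start", "end", "timepoint_s"]
        merged = deltas1.merge(deltas2, on=key, suffixes=("_a", "_b"))
        assert (merged["significant_a"] == merged["significant_b"]).all()


class TestDifferentialAnalysis:
    def test_threshold_override_respected(self, study_run):
        deltas, params = ht.differential_analysis(
            study_run["free"], study_run["bound"], threshold_override=0.3184
        )
        assert params.threshold == 0.3184

    def test_per_comparison_df_reproduces_point3_scale(self, study_run):
        _, params = ht.differential_analysis(
            study_run["free"], study_run["bound"],
            threshold_df="per_comparison",
        )
        # triplicates, s_pooled ~0.13 Da -> threshold near 0.3 Da
        expected = R_T975[4] * params.s_pooled * np.sqrt(2 / 3)
        assert params.threshold == pytest.approx(expected, abs=1e-9)
        assert 0.25 < params.threshold < 0.35

    def test_strict_alpha_preset_is_more_conservative(self, study_run):
        lax, _ = ht.differential_analysis(
            study_run["free"], study_run["bound"], alpha_ttest=0.05
        )
        strict, _ = ht.differential_analysis(
            study_run["free"], study_run["bound"], alpha_ttest=0.01
        )
        assert strict["significant"].sum() <= lax["significant"].sum()
        assert (strict["significant"] <= lax["significant"]).all()


def test_residual_csv_layout(tmp_path, study_run):
    path = tmp_path / "residuals.csv"
    write_residual_csv(study_run["deltas"], path)
    head = path.read_text().splitlines()[0]
    assert head == (
        "peptide_index,start,end,timepoint_s,delta_da,sum_delta_da,"
        "welch_p,significant,direction"
    )


def test_welch_agrees_with_scipy_oracle_on_random_instances():
    """Vectorized Welch path vs scipy.stats.ttest_ind on random draws."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        n1, n2 = rng.integers(2, 7, size=2)
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.05, 2.0), n1)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.05, 2.0), n2)
        t, df, p = ht.welch_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
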