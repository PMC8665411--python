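"""Outlier fences, the per-feature linear model, BH adjustment and the
composed differential analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lfqdiff import (
    QuantTable,
    RunConfig,
    Stage,
    ValidationError,
    adjust_bh,
    fit_feature_model,
    flag_condition_specific,
    make_builtin_designs,
    run_differential,
    simulate_experiment,
    tukey_fences_filter,
)
from lfqdiff.preprocess import FeatureGroup
from lfqdiff.simulate import TruthParams


def bh_literal(pvals: np.ndarray) -> np.ndarray:
    """Literal O(m^2) step-up definition used as the independent oracle:
    adj(i) = min over j with p(j) >= p(i) of min(1, m * p(j) / rank(j))."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=float)
    # ties share the largest rank among equal values (step-up equivalence)
    sorted_p = p[order]
    for pos, idx in enumerate(order):
        ranks[idx] = pos + 1
    adj = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        adj[i] = min(candidates)
    return adj


class TestTukeyFences:
    def test_hand_computed_example(self):
        mask = tukey_fences_filter([1, 2, 3, 4, 100], 1.5)
        # Q1=2, Q3=4 by linear interpolation; upper fence 4 + 1.5*2 = 7
        assert mask.tolist() == [True, True, True, True, False]

    def test_quartile_convention(self):
        assert np.percentile([1, 2, 3, 4], 25) == 1.75

    def test_zero_iqr_retains_everything(self):
        assert tukey_fences_filter([5, 5, 5, 5], 1.5).all()

    def test_infinite_fence_retains_everything(self):
        rng = np.random.default_rng(0)
        assert tukey_fences_filter(rng.normal(size=50), 1e6).all()

    def test_small_cells_unfiltered(self):
        assert tukey_fences_filter([0.0, 100.0, -100.0], 1.5).all()

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            tukey_fences_filter([1, 2, 3, 4], -0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        st.floats(1.5, 10),
    )
    def test_refiltering_with_same_fences_removes_nothing(self, values, k):
        v = np.asarray(values)
        q1, q3 = np.percentile(v, [25, 75])
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        kept = v[tukey_fences_filter(v, k)]
        assert ((kept >= lo) & (kept <= hi)).all()


def _obs(peptide_values: dict) -> pd.DataFrame:
    """peptide_values: pep -> (list_a, list_b)."""
    rows = []
    for pep, (va, vb) in peptide_values.items():
        rows += [{"peptide_key": pep, "condition": "parental", "value": v} for v in va]
        rows += [{"peptide_key": pep, "condition": "ko", "value": v} for v in vb]
    return pd.DataFrame(rows)


class TestFitFeatureModel:
    def test_noiseless_shift_recovered_exactly(self):
        obs = _obs({
            "p1": ([10.0, 11.0, 12.0], [11.0, 12.0, 13.0]),
            "p2": ([8.0, 9.0, 10.0], [9.0, 10.0, 11.0]),
        })
        fit = fit_feature_model(obs, "ko")
        assert fit.log2_fc == pytest.approx(1.0, abs=1e-12)

    def test_identical_samples_give_null(self):
        obs = _obs({"p1": ([10.0, 11.0, 12.0], [10.0, 11.0, 12.0])})
        fit = fit_feature_model(obs, "ko")
        assert fit.log2_fc == pytest.approx(0.0, abs=1e-12)
        assert fit.raw_p == pytest.approx(1.0)

    def test_single_peptide_equals_pooled_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(20, 1, 4), rng.normal(21, 1, 8)
        fit = fit_feature_model(_obs({"p1": (a.tolist(), b.tolist())}), "ko")
        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert fit.raw_p == pytest.approx(p, rel=1e-10)
        assert fit.log2_fc == pytest.approx(b.mean() - a.mean(), rel=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Three-peptide unbalanced group vs an independent least-squares
        solve of the same design matrix."""
        rng = np.random.default_rng(17)
        peps = {}
        for i, pep in enumerate(["p1", "p2", "p3"]):
            na, nb = rng.integers(2, 5), rng.integers(2, 6)
            peps[pep] = (
                (rng.normal(20 + i, 0.5, na)).tolist(),
                (rng.normal(20.7 + i, 0.5, nb)).tolist(),
            )
        obs = _obs(peps)
        fit = fit_feature_model(obs, "ko")

        dummies = pd.get_dummies(obs["peptide_key"], drop_first=True, dtype=float)
        X = np.column_stack(
            [np.ones(len(obs)), dummies.to_numpy(),
             (obs["condition"] == "ko").to_numpy(dtype=float)]
        )
        y = obs["value"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = len(obs) - X.shape[1]
        se = np.sqrt(resid @ resid / df * np.linalg.inv(X.T @ X)[-1, -1])
        p = 2 * stats.t.sf(abs(beta[-1]) / se, df)
        assert fit.log2_fc == pytest.approx(beta[-1], abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.raw_p == pytest.approx(p, abs=1e-10)

    def test_zero_residual_df_gives_missing_p(self):
        obs = _obs({"p1": ([10.0], [11.0])})
        fit = fit_feature_model(obs, "ko")
        assert np.isnan(fit.raw_p)
        assert fit.log2_fc == pytest.approx(1.0)


class TestAdjustBH:
    def test_hand_step_up(self):
        # ranks 1..3: 3*0.01/1=0.03, 3*0.03/2=0.045 -> min with next = 0.04
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_singleton_identity(self):
        assert adjust_bh([0.5]).tolist() == [0.5]

    def test_missing_excluded_from_family(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_literal_definition(self, pvals):
        np.testing.assert_allclose(
            adjust_bh(pvals), bh_literal(np.array(pvals)), atol=1e-12
        )

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestConditionSpecific:
    def _group(self, condition):
        obs = pd.DataFrame(
            {
                "peptide_key": ["p1"] * 3,
                "condition": [condition] * 3,
                "bio_rep": [1, 2, 3],
                "value": [20.0, 20.5, 21.0],
            }
        )
        return FeatureGroup(
            feature_id="F", protein_id="F", level="protein",
            observations=obs, shared_peptides=frozenset(),
            specific_candidate=True, detect_reps={},
        )

    def test_only_in_ko_is_b_only(self, designs):
        assert flag_condition_specific(self._group("ko"), designs["panub"]) == "b_only"

    def test_only_in_parental_is_a_only(self, designs):
        assert (
            flag_condition_specific(self._group("parental"), designs["panub"])
            == "a_only"
        )

    def test_both_conditions_is_contract_violation(self, designs):
        g = self._group("ko")
        g.observations.loc[0, "condition"] = "parental"
        with pytest.raises(ValidationError):
            flag_condition_specific(g, designs["panub"])


class TestRunDifferential:
    def test_fixture_flags_and_counts(self, toy_results):
        res = toy_results.set_index("feature_id")
        assert res.loc["SPA1", "specific_flag"] == "a_only"
        assert res.loc["SPB1", "specific_flag"] == "b_only"
        assert np.isnan(res.loc["SPA1", "log2_fc"])
        assert res.loc["UPQ1", "detect_reps_a"] == 4
        assert res.loc["UPQ1", "detect_reps_b"] == 8
        assert res.loc["SPB1", "detect_reps_b"] == 8

    def test_adjusted_p_not_below_raw(self, toy_results):
        both = toy_results.dropna(subset=["raw_p", "adj_p"])
        assert (both["adj_p"] >= both["raw_p"] - 1e-15).all()

    def test_fixture_effects_recovered_at_tolerance(self, toy_results, toy):
        res = toy_results.set_index("feature_id")
        assert res.loc["UPQ1", "log2_fc"] == pytest.approx(2.0, abs=0.35)
        assert res.loc["DWN1", "log2_fc"] == pytest.approx(-2.0, abs=0.35)
        assert res.loc["NUL1", "adj_p"] > 0.05
        assert res.loc["NUL2", "adj_p"] > 0.05

    def test_condition_swap_negates_folds(self, designs):
        params = TruthParams(n_features=60, seed=21)
        table, _ = simulate_experiment(designs["panub"], params)
        fwd = run_differential(table)
        swapped = QuantTable(
            design=table.design.swapped(), data=table.data, stage=table.stage
        )
        rev = run_differential(swapped)
        j = fwd.merge(rev, on="feature_id", suffixes=("_f", "_r"))
        tested = j["raw_p_f"].notna()
        assert np.allclose(
            j.loc[tested, "log2_fc_f"], -j.loc[tested, "log2_fc_r"], atol=1e-12
        )
        assert np.allclose(
            j.loc[tested, "raw_p_f"], j.loc[tested, "raw_p_r"], atol=1e-12
        )

    def test_outlier_shifted_observation_removed(self, designs):
        """A grossly shifted peptide is fenced out and the estimate protected."""
        params = TruthParams(
            n_features=1, peptides_per_feature=(6, 6), frac_changed=0,
            frac_specific_a=0, frac_specific_b=0, sigma_rep=0,
            sigma_noise=0.05, sigma_tech=0, outlier_rate=0,
            missing_rate_base=0, seed=2,
        )
        table, _ = simulate_experiment(designs["panub"], params)
        df = table.data.copy()
        bad = df["peptide_key"] == df["peptide_key"].iloc[0]
        df.loc[bad & (df["condition"] == "ko"), "xic"] *= 2.0 ** 6
        poisoned = QuantTable(table.design, df, table.stage)
        res_fenced = run_differential(
            poisoned, RunConfig(normalize=False)
        ).iloc[0]
        res_open = run_differential(
            poisoned, RunConfig(fence_k=1e9, normalize=False)
        ).iloc[0]
        assert res_fenced["n_obs_removed_outlier"] > 0
        assert abs(res_fenced["log2_fc"]) < abs(res_open["log2_fc"])
        assert abs(res_fenced["log2_fc"]) < 0.2

    def test_insufficient_data_yields_missing_result(self, designs):
        from lfqdiff.datamodel import empty_quant_frame

        rows = []
        for cond, rep in (("parental", 1), ("ko", 1)):
            rows.append(
                {
                    "protein_id": "P1", "gene_symbol": "", "peptide_key": "p1",
                    "is_proteotypic": True, "gg_positions": (),
                    "condition": cond, "bio_rep": rep, "tech_rep": 1,
                    "fraction": 1, "xic": 100.0,
                }
            )
        df = pd.concat([empty_quant_frame(), pd.DataFrame(rows)], ignore_index=True)
        for col in ("bio_rep", "tech_rep", "fraction"):
            df[col] = df[col].astype(np.int64)
        table = QuantTable(designs["panub"], df, Stage.TECH_MERGED)
        res = run_differential(table, RunConfig(normalize=False))
        assert len(res) == 1
        assert np.isnan(res["raw_p"].iloc[0])
        assert res["specific_flag"].iloc[0] == "none"
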