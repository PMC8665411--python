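"""Candidate criteria, site-to-protein collapse, overlaps, stars, heatmap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfqdiff import (
    ConfigError,
    RunConfig,
    ValidationError,
    build_heatmap_table,
    collapse_sites_to_proteins,
    format_significance_stars,
    intersect_candidates,
    select_candidates,
)
from lfqdiff.candidates import CandidateSet


def _results(rows, level="protein"):
    base = {
        "feature_id": "F", "protein_id": "F", "gene_symbol": "", "level": level,
        "log2_fc": 0.0, "se": 0.1, "raw_p": 0.5, "adj_p": 0.5,
        "n_peptides_used": 2, "n_obs_removed_outlier": 0,
        "detect_reps_a": 4, "detect_reps_b": 8, "specific_flag": "none",
    }
    out = []
    for i, r in enumerate(rows):
        row = {**base, "feature_id": f"F{i}", "protein_id": f"F{i}"}
        row.update(r)
        out.append(row)
    return pd.DataFrame(out)


CFG = RunConfig()


class TestSelectCandidates:
    def test_passing_decrease_member(self):
        res = _results([{"log2_fc": -1.2, "adj_p": 0.01, "detect_reps_a": 3,
                         "detect_reps_b": 0}])
        cset = select_candidates(res, CFG, direction="decrease")
        assert cset.member_ids == ["F0"]

    def test_fails_alpha(self):
        res = _results([{"log2_fc": -1.2, "adj_p": 0.2}])
        assert select_candidates(res, CFG, direction="decrease").member_ids == []

    def test_fails_fold(self):
        # |fold| = 2**0.9 = 1.87 < 2 despite tiny p
        res = _results([{"log2_fc": -0.9, "adj_p": 0.001}])
        assert select_candidates(res, CFG, direction="decrease").member_ids == []
        assert 2 ** 0.9 < 2

    def test_wrong_sign_excluded(self):
        res = _results([{"log2_fc": 1.5, "adj_p": 0.001}])
        assert select_candidates(res, CFG, direction="decrease").member_ids == []

    def test_boundaries_inclusive(self):
        res = _results(
            [{"log2_fc": 1.0, "adj_p": 0.05}, {"log2_fc": math.log2(2) - 1e-9,
                                               "adj_p": 0.05}]
        )
        cset = select_candidates(res, CFG, direction="increase")
        assert cset.member_ids == ["F0"]  # exactly 2-fold and p = 0.05 admitted

    def test_detection_filter_uses_either_condition(self):
        res = _results(
            [
                {"log2_fc": 1.5, "adj_p": 0.01, "detect_reps_a": 1,
                 "detect_reps_b": 3},
                {"log2_fc": 1.5, "adj_p": 0.01, "detect_reps_a": 2,
                 "detect_reps_b": 2},
            ]
        )
        cset = select_candidates(res, CFG, direction="increase")
        assert cset.member_ids == ["F0"]

    def test_specific_direction_mapping(self):
        res = _results(
            [
                {"specific_flag": "b_only", "log2_fc": np.nan, "adj_p": np.nan,
                 "detect_reps_a": 0, "detect_reps_b": 5},
                {"specific_flag": "a_only", "log2_fc": np.nan, "adj_p": np.nan,
                 "detect_reps_a": 4, "detect_reps_b": 0},
            ]
        )
        inc = select_candidates(res, CFG, direction="increase")
        dec = select_candidates(res, CFG, direction="decrease")
        assert inc.member_ids == ["F0"] and inc.specific_member_ids == ["F0"]
        assert dec.member_ids == ["F1"]

    def test_specific_detection_in_own_condition(self):
        res = _results(
            [{"specific_flag": "b_only", "log2_fc": np.nan, "adj_p": np.nan,
              "detect_reps_a": 0, "detect_reps_b": 2}]
        )
        assert select_candidates(res, CFG, direction="increase").member_ids == []

    def test_direction_required(self):
        with pytest.raises(ConfigError):
            select_candidates(_results([{}]), RunConfig())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.01, 0.2),
        fold=st.floats(1.1, 4.0),
        looser_alpha=st.floats(0.0, 0.3),
        looser_fold=st.floats(0.0, 1.0),
    )
    def test_monotone_in_thresholds(self, alpha, fold, looser_alpha, looser_fold):
        """Relaxing alpha or the fold threshold never removes members."""
        rng = np.random.default_rng(99)
        res = _results(
            [
                {"log2_fc": fc, "adj_p": p}
                for fc, p in zip(
                    rng.normal(0, 1.5, 40), rng.uniform(0, 0.3, 40)
                )
            ]
        )
        tight = RunConfig(fold_threshold=fold + looser_fold,
                          alpha=max(alpha - looser_alpha, 1e-6))
        loose = RunConfig(fold_threshold=fold, alpha=alpha)
        got_tight = set(select_candidates(res, tight, direction="increase").member_ids)
        got_loose = set(select_candidates(res, loose, direction="increase").member_ids)
        assert got_tight <= got_loose


def _cset(ids, level="protein", proteins=None):
    members = pd.DataFrame(
        {
            "feature_id": ids,
            "protein_id": proteins if proteins is not None else ids,
            "level": level,
            "log2_fc": -1.5,
            "adj_p": 0.01,
            "specific_flag": "none",
        }
    )
    return CandidateSet(
        experiment="x", direction="decrease", fold_threshold=2.0, alpha=0.05,
        min_detect_reps=3, members=members, level=level,
    )


class TestCollapseAndIntersect:
    def test_collapse_projects_distinct_proteins(self):
        cset = _cset(
            ["P2_K343", "P1_K10", "P1_K99"], level="site",
            proteins=["P2", "P1", "P1"],
        )
        proteins, mapping = collapse_sites_to_proteins(cset)
        assert proteins == {"P2", "P1"}
        assert len(mapping) == 3  # provenance keeps every site

    def test_collapse_empty(self):
        proteins, mapping = collapse_sites_to_proteins(_cset([], level="site"))
        assert proteins == set() and len(mapping) == 0

    def test_collapse_never_increases_count(self, designs):
        from lfqdiff import run_differential, simulate_experiment
        from lfqdiff.simulate import TruthParams

        table, _ = simulate_experiment(
            designs["digly"],
            TruthParams(n_features=40, frac_changed=0.3, log2fc_changed=-2.5,
                        seed=13),
        )
        res = run_differential(table)
        cset = select_candidates(res, CFG, direction="decrease")
        proteins, _ = collapse_sites_to_proteins(cset)
        assert len(proteins) <= len(cset)

    def test_pairwise_and_common_intersections(self):
        report = intersect_candidates(
            {"e1": ["A", "B", "C", "D"], "e2": ["C", "D", "E"]}
        )
        assert report.overlap("e1", "e2") == ["C", "D"]
        assert report.common == ["C", "D"]
        assert report.counts == {"e1": 4, "e2": 3}

    def test_disjoint_sets(self):
        report = intersect_candidates({"e1": ["A"], "e2": ["B"], "e3": ["C"]})
        assert report.common == []
        assert all(not v for v in report.pairwise.values())

    def test_three_way_structure(self):
        report = intersect_candidates(
            {
                "proteome": ["C1", "C2", "X1", "X2"],
                "digly": ["C1", "C2", "Y1", "Z1", "Z2", "Z3"],
                "panub": ["C1", "C2", "Z1", "Z2", "Z3", "W1"],
            }
        )
        assert report.overlap("proteome", "digly") == ["C1", "C2"]
        assert report.overlap("proteome", "panub") == ["C1", "C2"]
        assert report.overlap("digly", "panub") == ["C1", "C2", "Z1", "Z2", "Z3"]
        assert report.common == ["C1", "C2"]


class TestStarsAndHeatmap:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
            (0.03, "*"), (0.05, "*"), (0.2, ""), (np.nan, ""), (None, ""),
        ],
    )
    def test_star_thresholds(self, p, stars):
        assert format_significance_stars(p) == stars

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            format_significance_stars(1.5)

    def test_heatmap_cells(self):
        res_a = _results(
            [
                {"log2_fc": 1.0, "adj_p": 0.03},
                {"specific_flag": "b_only", "log2_fc": np.nan, "adj_p": np.nan},
            ]
        )
        res_b = _results([{"log2_fc": -2.0, "adj_p": 0.0005}])
        report = intersect_candidates({"expA": res_a["feature_id"],
                                       "expB": res_b["feature_id"]})
        table = build_heatmap_table({"expA": res_a, "expB": res_b}, report)
        row0 = table[table["feature_id"] == "F0"].iloc[0]
        assert row0["expA_fold"] == pytest.approx(2.0)
        assert row0["expA_direction"] == "increase"
        assert row0["expA_stars"] == "*"
        assert row0["expB_fold"] == pytest.approx(4.0)
        assert row0["expB_direction"] == "decrease"
        assert row0["expB_stars"] == "***"
        row1 = table[table["feature_id"] == "F1"].iloc[0]
        assert row1["expA_direction"] == "specific" and row1["expA_stars"] == ""
        assert row1["expB_direction"] == "" and np.isnan(row1["expB_fold"])
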