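import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hspcmeth as h
from hspcmeth.beta_io import HYPER, HYPO
from .conftest import HSPC_TYPES, LEUKO_GROUPS


def two_group_matrix(target_vals, rest_vals, cpg_ids=None):
    """Build a matrix + annotation with one row per CpG from value lists."""
    target_vals = np.atleast_2d(target_vals)
    rest_vals = np.atleast_2d(rest_vals)
    n_cpg = target_vals.shape[0]
    cpg_ids = cpg_ids or [f"cg{i:03d}" for i in range(n_cpg)]
    data = {}
    for j in range(target_vals.shape[1]):
        data[f"t{j}"] = target_vals[:, j]
    for j in range(rest_vals.shape[1]):
        data[f"r{j}"] = rest_vals[:, j]
    beta = h.BetaMatrix(pd.DataFrame(data, index=cpg_ids))
    labels = ["HSPC"] * target_vals.shape[1] + ["leuko"] * rest_vals.shape[1]
    ann = h.SampleAnnotation.from_labels(list(beta.sample_ids), labels)
    return beta, ann


class TestGroupStats:
    def test_extreme_separation(self):
        beta, ann = two_group_matrix([[1.0, 1.0]], [[0.0, 0.0]])
        stats = h.group_stats(beta, ann, "HSPC")
        row = stats.iloc[0]
        assert row["delta"] == 1.0
        assert row["sd_target"] == 0.0 and row["sd_rest"] == 0.0

    def test_identical_groups_give_zero_delta(self):
        vals = np.array([[0.3, 0.5], [0.8, 0.6]])
        beta, ann = two_group_matrix(vals, vals)
        stats = h.group_stats(beta, ann, "HSPC")
        assert (stats["delta"] == 0.0).all()

    def test_hand_computed_means_and_sds(self):
        # target {0.8, 0.9}, rest {0.1, 0.2}: delta 0.70, sample sd 0.0707
        beta, ann = two_group_matrix([[0.8, 0.9]], [[0.1, 0.2]])
        row = h.group_stats(beta, ann, "HSPC").iloc[0]
        assert row["delta"] == pytest.approx(0.70)
        assert row["sd_target"] == pytest.approx(0.070710678, abs=1e-9)
        assert row["sd_rest"] == pytest.approx(0.070710678, abs=1e-9)
        assert row["n_target"] == 2 and row["n_rest"] == 2

    def test_target_overlapping_rest_rejected(self):
        beta, ann = two_group_matrix([[0.8, 0.9]], [[0.1, 0.2]])
        with pytest.raises(h.ValidationError, match="overlap"):
            h.group_stats(beta, ann, "HSPC", rest_groups=["HSPC", "leuko"])

    def test_single_sample_group_rejected(self):
        beta, ann = two_group_matrix([[0.8]], [[0.1, 0.2]])
        with pytest.raises(h.ValidationError, match="at least 2"):
            h.group_stats(beta, ann, "HSPC")

    def test_high_missingness_cpg_dropped(self):
        vals_t = np.array([[0.8, np.nan, np.nan, np.nan], [0.5, 0.5, 0.5, 0.5]])
        vals_r = np.array([[0.1, 0.1, 0.1, 0.1], [0.2, 0.2, 0.2, 0.2]])
        beta, ann = two_group_matrix(vals_t, vals_r)
        stats = h.group_stats(beta, ann, "HSPC")
        assert list(stats.index) == ["cg001"]

    def test_swap_negates_delta_keeps_sds(self):
        rng = np.random.default_rng(7)
        beta, ann = two_group_matrix(rng.random((5, 3)), rng.random((5, 4)))
        fwd = h.group_stats(beta, ann, "HSPC")
        rev = h.group_stats(beta, ann, "leuko")
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        np.testing.assert_allclose(fwd["sd_target"], rev["sd_rest"], atol=1e-12)
        np.testing.assert_allclose(fwd["sd_rest"], rev["sd_target"], atol=1e-12)


class TestRankCandidates:
    def stats_frame(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["mean_target", "mean_rest", "sd_target", "sd_rest"],
            index=[f"cg{i:03d}" for i in range(len(rows))],
        )
        df["delta"] = df["mean_target"] - df["mean_rest"]
        df["n_target"] = df["n_rest"] = 3
        df.index.name = "cpg_id"
        return df[h.marker_selection.STAT_COLUMNS]

    def test_single_cpg_ranks_first(self):
        stats = self.stats_frame([[0.9, 0.1, 0.2, 0.2]])
        out = h.rank_candidates(stats, "both", 1)
        assert list(out.index) == ["cg000"]

    def test_brute_force_score_ordering(self):
        # (|delta|, max sd): (0.9, 0.05) → 0.85; (0.95, 0.30) → 0.65;
        # (0.5, 0.01) → 0.49
        stats = self.stats_frame(
            [[0.9, 0.0, 0.05, 0.02], [0.95, 0.0, 0.30, 0.10], [0.5, 0.0, 0.01, 0.005]]
        )
        out = h.rank_candidates(stats, "both", 3)
        assert out["score"].tolist() == pytest.approx([0.85, 0.65, 0.49])
        assert list(out.index) == ["cg000", "cg001", "cg002"]

    def test_direction_assignment_and_filter(self):
        stats = self.stats_frame([[0.9, 0.1, 0.0, 0.0], [0.1, 0.9, 0.0, 0.0]])
        hyper = h.rank_candidates(stats, HYPER)
        hypo = h.rank_candidates(stats, HYPO)
        assert list(hyper.index) == ["cg000"]
        assert list(hypo.index) == ["cg001"]

    def test_overlong_request_warns_and_returns_all(self):
        stats = self.stats_frame([[0.9, 0.1, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="only 1"):
            out = h.rank_candidates(stats, "both", 5)
        assert len(out) == 1

    def test_ties_broken_by_absdelta_then_id(self):
        # binary-exact score ties: 0.75−0.25 = 0.875−0.375 = 0.5
        # → larger |delta| first, then lexicographic CpG id
        stats = self.stats_frame(
            [
                [0.75, 0.0, 0.25, 0.25],
                [0.875, 0.0, 0.375, 0.25],
                [0.875, 0.0, 0.375, 0.0],
            ]
        )
        out = h.rank_candidates(stats, "both")
        assert list(out.index) == ["cg001", "cg002", "cg000"]

    def test_score_invariant_to_row_and_sample_order(self):
        rng = np.random.default_rng(11)
        beta, ann = two_group_matrix(rng.random((6, 3)), rng.random((6, 3)))
        stats = h.group_stats(beta, ann, "HSPC")
        shuffled = h.BetaMatrix(
            beta.data.iloc[::-1][list(beta.sample_ids)[::-1]]
        )
        stats2 = h.group_stats(shuffled, ann, "HSPC")
        out1 = h.rank_candidates(stats, "both")
        out2 = h.rank_candidates(stats2, "both")
        pd.testing.assert_frame_equal(out1, out2)

    @given(
        delta=st.floats(-1, 1),
        sd_t=st.floats(0, 0.5),
        sd_r=st.floats(0, 0.5),
        w=st.floats(0, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_score_bounded_above_by_absdelta(self, delta, sd_t, sd_r, w):
        mean_rest = 0.0 if delta >= 0 else -delta
        stats = self.stats_frame([[mean_rest + delta, mean_rest, sd_t, sd_r]])
        out = h.rank_candidates(stats, "both", weight=w)
        assert out["score"].iloc[0] <= abs(delta) + 1e-12 <= 1 + 1e-12


class TestParetoFront:
    def test_dominated_point_excluded(self):
        stats = TestRankCandidates().stats_frame(
            [[0.9, 0.0, 0.05, 0.0], [0.8, 0.0, 0.10, 0.0], [0.5, 0.0, 0.01, 0.0]]
        )
        front = h.pareto_front(stats)
        # cg001 is dominated by cg000 (smaller delta, larger sd)
        assert front.tolist() == [True, False, True]

    def test_duplicate_points_both_on_front(self):
        stats = TestRankCandidates().stats_frame(
            [[0.9, 0.0, 0.05, 0.0], [0.9, 0.0, 0.05, 0.0]]
        )
        assert h.pareto_front(stats).all()


class TestPlantedMarkerRecovery:
    def test_planted_hspc_markers_outrank_background(self):
        spec = h.SyntheticSpec(
            n_cell_types=2,
            cell_type_names=["HSPC", "leukocyte"],
            n_background_cpgs=500,
            markers_per_type=(3, 3),
            marker_delta=0.6,
            within_type_sd=0.02,
            samples_per_type=5,
            seed=42,
        )
        beta, ann, truth = h.make_reference_profiles(spec)
        stats = h.group_stats(beta, ann, "HSPC")
        ranked = h.rank_candidates(stats, "both")
        # with two groups, every planted marker (either type's) separates
        # them; all planted markers must outrank all background CpGs
        planted = set(truth)
        assert set(ranked.index[: len(planted)]) == planted
        # CpGs hypermethylated in HSPCs = HSPC-hyper or leukocyte-hypo plants
        hyper = h.rank_candidates(stats, HYPER, 3)
        for c in hyper.index:
            t = truth[c]
            assert (t["cell_type"], t["direction"]) in {
                ("HSPC", HYPER),
                ("leukocyte", HYPO),
            }


class TestSubsetSelection:
    def test_reduces_to_rank_candidates_for_single_subset(self, reference_data):
        beta, ann, _ = reference_data
        result = h.select_subset_markers(beta, ann, ["HSC"], n_hypo=2, n_hyper=2)
        stats = h.group_stats(beta, ann, "HSC")
        expect_hyper = h.rank_candidates(stats, HYPER, 2)
        expect_hypo = h.rank_candidates(stats, HYPO, 2)
        got = result["HSC"]
        assert set(got.index) == set(expect_hyper.index) | set(expect_hypo.index)

    def test_planted_markers_recovered_per_subset(self, reference_data):
        beta, ann, truth = reference_data
        result = h.select_subset_markers(beta, ann, HSPC_TYPES)
        for subset in HSPC_TYPES:
            got = set(result[subset].index)
            planted = {c for c, t in truth.items() if t["cell_type"] == subset}
            assert got == planted

    def test_default_design_is_18_cpgs_over_3_subsets(self, reference_data):
        beta, ann, _ = reference_data
        result = h.select_subset_markers(beta, ann, HSPC_TYPES)
        all_ids = [c for s in HSPC_TYPES for c in result[s].index]
        assert len(all_ids) == 18
        assert len(set(all_ids)) == 18  # cross-subset uniqueness

    def test_each_subset_gets_three_per_direction(self, reference_data):
        beta, ann, _ = reference_data
        result = h.select_subset_markers(beta, ann, HSPC_TYPES)
        for subset in HSPC_TYPES:
            counts = result[subset]["direction"].value_counts()
            assert counts[HYPER] == 3 and counts[HYPO] == 3


class TestMarkerSelectorEstimator:
    def test_fit_transform_selects_planted_markers(self, reference_data):
        beta, ann, truth = reference_data
        X = beta.samples_frame()
        y = [ann.group_of(s) for s in X.index]
        sel = h.MarkerSelector(target_group="HSC", n_top=6).fit(X, y)
        planted = {c for c, t in truth.items() if t["cell_type"] == "HSC"}
        assert set(sel.selected_ids_) == planted
        Xt = sel.transform(X)
        assert list(Xt.columns) == sel.selected_ids_
        assert sel.get_support().sum() == 6

    def test_sklearn_param_round_trip(self):
        sel = h.MarkerSelector(target_group="HSC", n_top=4, weight=0.5)
        params = sel.get_params()
        clone = h.MarkerSelector(**params)
        assert clone.get_params() == params

    def test_transform_before_fit_raises(self):
        with pytest.raises(h.ValidationError, match="not fitted"):
            h.MarkerSelector(target_group="x").transform(pd.DataFrame())
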