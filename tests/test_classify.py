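"""Class assignment, K-Means boundary calibration and expert-label
consolidation, checked against exhaustive partition search."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rehabmcdm as rm

# Second-assessment reference classes of the packaged cohort, patients 1..20
II_CLASSES = [4, 4, 3, 4, 3, 2, 3, 2, 4, 3, 3, 4, 3, 3, 4, 2, 4, 3, 2, 4]


def best_contiguous_sse(values, k):
    """Oracle: exhaustive search over contiguous partitions of sorted values."""
    sv = np.sort(np.asarray(values, float))
    n = len(sv)

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        idx = [0, *cuts, n]
        total = sum(sse(sv[idx[i]:idx[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


class TestAssignClass:
    @pytest.mark.parametrize("score,cls", [
        (0.6912, 4),   # patient 17, second assessment
        (0.4073, 2),   # patient 6, second assessment
        (1.0, 5),
        (0.01, 1),
        (0.4915, 3),   # rounding-gap value goes to the upper class
        (0.3169, 2),   # closed lower endpoint
    ])
    def test_expert_boundary_assignments(self, score, cls):
        assert rm.assign_class(score, rm.datasets.expert_boundaries()) == cls

    def test_score_outside_range_errors(self):
        model = rm.datasets.expert_boundaries()
        with pytest.raises(ValueError, match="0.001"):
            rm.assign_class(0.001, model)
        with pytest.raises(ValueError, match="1.2"):
            rm.assign_class(1.2, model)

    def test_second_assessment_distribution(self, patient_scores):
        sub = patient_scores[patient_scores["assessment"] == "II"]["score"]
        counts = rm.class_distribution(sub, rm.datasets.expert_boundaries())
        assert counts.tolist() == [0, 4, 8, 8, 0]

    def test_first_assessment_moderate_count(self, patient_scores):
        sub = patient_scores[patient_scores["assessment"] == "I"]["score"]
        counts = rm.class_distribution(sub, rm.datasets.expert_boundaries())
        assert counts[2] == 7  # moderate impairment (class III)

    def test_per_patient_classes_match_recorded_labels(self, patient_scores, votes):
        model = rm.datasets.expert_boundaries()
        sub = patient_scores[patient_scores["assessment"] == "II"].reset_index(drop=True)
        assigned = [rm.assign_class(s, model) for s in sub["score"]]
        assert assigned == II_CLASSES
        ref = votes.frame[votes.frame["assessment"] == "II"]["reference"].tolist()
        assert assigned == ref

    def test_empty_score_list_all_zero(self):
        counts = rm.class_distribution([], rm.datasets.expert_boundaries())
        assert counts.tolist() == [0, 0, 0, 0, 0]


class TestKmeans1d:
    def test_well_separated_groups(self):
        vals = [0, 0.01, 1, 1.01, 2, 2.01]
        cm = rm.kmeans_1d(vals, 3, seed=0)
        assert [tuple(cm.members(i)) for i in range(3)] == [
            (0, 0.01), (1, 1.01), (2, 2.01)]

    def test_single_cluster_closed_form(self):
        vals = np.array([1.0, 2.0, 4.0, 7.0])
        cm = rm.kmeans_1d(vals, 1, seed=0)
        assert cm.centroids[0] == pytest.approx(vals.mean())
        assert cm.sse == pytest.approx(((vals - vals.mean()) ** 2).sum())

    def test_k_above_distinct_values_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            rm.kmeans_1d([1.0, 1.0, 2.0], 3)

    def test_sse_consistent_with_assignments(self, corrected_values):
        cm = rm.kmeans_1d(corrected_values, 5, seed=0)
        recomputed = sum(
            float(((cm.members(i) - cm.members(i).mean()) ** 2).sum())
            for i in range(5)
        )
        assert cm.sse == pytest.approx(recomputed, rel=1e-9)

    def test_determinism_given_seed(self, corrected_values):
        a = rm.kmeans_1d(corrected_values, 5, seed=11)
        b = rm.kmeans_1d(corrected_values, 5, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert a.sse == b.sse

    @pytest.mark.parametrize("n,k,seed", [(7, 2, 0), (10, 3, 1), (12, 3, 2), (9, 2, 3)])
    def test_matches_exhaustive_partition_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(0, 1, n), 3)
        cm = rm.kmeans_1d(vals, k, n_restarts=50, seed=0)
        assert cm.sse == pytest.approx(best_contiguous_sse(vals, k), abs=1e-9)


class TestCalibration:
    def test_corrected_value_set_composition(self, cohort_scores):
        vals = rm.corrected_value_set(
            cohort_scores[cohort_scores["assessment"] == "I"]["score"],
            cohort_scores[cohort_scores["assessment"] == "II"]["score"],
        )
        assert len(vals) == 43
        assert vals.min() == 0.01 and vals.max() == 1.0
        assert (vals == 1.0).sum() == 2  # healthy at both assessments, kept as multiset

    def test_corrected_value_set_empty_cohort(self):
        vals = rm.corrected_value_set([1.0], [1.0])
        assert sorted(vals) == [0.01, 1.0, 1.0]

    def test_second_cluster_starts_at_outlier_score(self, corrected_values):
        cm = rm.kmeans_1d(corrected_values, 5, n_restarts=50, seed=0)
        assert rm.clusters_to_intervals(cm)[1][0] == pytest.approx(0.2935)

    def test_clusters_to_intervals_trivial(self):
        cm = rm.kmeans_1d([0.0, 0.01, 1.0], 2, seed=0)
        assert rm.clusters_to_intervals(cm) == [(0.0, 0.01), (1.0, 1.0)]

    def test_gap_halving_internal_boundary(self):
        # gap between 0.4712 and 0.5099 splits at 0.49055
        model = rm.adjust_intervals([(0.2935, 0.4712), (0.5099, 0.6468)],
                                    rounding=3)
        (lo1, hi1), (lo2, hi2) = model.intervals
        assert hi1 == pytest.approx(0.490) and lo2 == pytest.approx(0.491)

    def test_tight_gap_backs_off_one_tick(self):
        # midpoint 0.6690 rounds onto a tick: upper keeps it, lower backs off
        model = rm.adjust_intervals([(0.5099, 0.6468), (0.6912, 0.8179)],
                                    rounding=3)
        (_, hi1), (lo2, _) = model.intervals
        assert lo2 == pytest.approx(0.669) and hi1 == pytest.approx(0.668)

    def test_contiguous_intervals_unchanged(self):
        model = rm.adjust_intervals([(0.0, 0.499), (0.5, 1.0)], rounding=3)
        assert model.intervals == ((0.0, 0.499), (0.5, 1.0))

    def test_overlapping_raw_intervals_rejected(self):
        with pytest.raises(rm.ClassModelError, match="disjoint"):
            rm.adjust_intervals([(0.0, 0.5), (0.4, 1.0)])

    def test_degenerate_extreme_clusters_anchor_boundaries(self):
        raw = [(0.01, 0.01), (0.2935, 0.4712), (0.5099, 0.6468),
               (0.6912, 0.8179), (1.0, 1.0)]
        model = rm.adjust_intervals(raw, rounding=3)
        assert model.intervals[0] == (0.01, pytest.approx(0.2934))
        assert model.intervals[1][0] == pytest.approx(0.2935)
        assert model.intervals[3][1] == pytest.approx(0.8179)
        assert model.intervals[4] == (pytest.approx(0.818), 1.0)

    def test_full_kmeans_model_matches_published_boundaries(self, corrected_values):
        model = rm.kmeans_class_model(corrected_values, seed=0)
        published = rm.datasets.kmeans_boundaries()
        for (lo, hi), (plo, phi) in zip(model.intervals, published.intervals):
            assert lo == pytest.approx(plo, abs=1.1e-3)
            assert hi == pytest.approx(phi, abs=1.1e-3)

    def test_members_stay_inside_their_class(self, corrected_values):
        cm = rm.kmeans_1d(corrected_values, 5, seed=0)
        model = rm.adjust_intervals(rm.clusters_to_intervals(cm))
        for i in range(5):
            for v in cm.members(i):
                assert rm.assign_class(v, model) == i + 1


class TestExpertConsolidation:
    @pytest.mark.parametrize("votes_row,expected", [
        ((2, 3, 2), 2),   # majority
        ((3, 3, 4), 3),
        ((2, 3), 2),      # tie -> worse (lower) class
        ((4,), 4),
    ])
    def test_majority_with_worse_tie_break(self, votes_row, expected):
        frame = pd.DataFrame([{
            "patient": "p", "assessment": "I", "reference": expected,
            **{f"expert_{i+1}": v for i, v in enumerate(votes_row)},
        }])
        res = rm.consensus_class(rm.ExpertVotes(frame))
        assert res.consensus.iloc[0] == expected

    def test_recorded_discrepancies_are_reported(self, votes):
        res = rm.consensus_class(votes)
        flagged = set(map(tuple, res.discrepancies[["patient", "assessment"]].values))
        # three rows of the packaged table disagree with their own votes
        assert flagged == {("19", "I"), ("16", "II"), ("19", "II")}

    def test_single_rejected_outlier(self, votes, patient_scores):
        report = rm.reject_outliers(votes, patient_scores)
        assert len(report.rejected) == 1
        assert report.rejected.iloc[0]["score"] == pytest.approx(0.2935)
        assert len(report.kept) == 39

    def test_concordant_votes_reject_nothing(self):
        frame = pd.DataFrame([
            {"patient": str(i), "assessment": "I", "reference": c,
             "expert_1": c, "expert_2": c, "expert_3": c}
            for i, c in enumerate([2, 2, 3, 3, 4])
        ])
        scores = pd.DataFrame({
            "patient": [str(i) for i in range(5)], "assessment": "I",
            "score": [0.3, 0.4, 0.5, 0.6, 0.7],
        })
        report = rm.reject_outliers(rm.ExpertVotes(frame), scores)
        assert report.rejected.empty

    def test_identical_labels_reject_nothing(self):
        frame = pd.DataFrame([
            {"patient": str(i), "assessment": "I", "reference": 3,
             "expert_1": 3, "expert_2": 3, "expert_3": 3}
            for i in range(4)
        ])
        scores = pd.DataFrame({
            "patient": [str(i) for i in range(4)], "assessment": "I",
            "score": [0.5, 0.55, 0.6, 0.65],
        })
        assert rm.reject_outliers(rm.ExpertVotes(frame), scores).rejected.empty

    def test_derived_expert_model_matches_published(self, votes, patient_scores):
        model = rm.expert_class_model(votes, patient_scores)
        published = rm.datasets.expert_boundaries()
        for (lo, hi), (plo, phi) in zip(model.intervals, published.intervals):
            assert lo == pytest.approx(plo, abs=1.1e-3)
            assert hi == pytest.approx(phi, abs=1.1e-3)


class TestCompareModels:
    def test_identical_models_agree_fully(self, patient_scores):
        m = rm.datasets.expert_boundaries()
        rep = rm.compare_models(m, m, patient_scores["score"])
        assert rep.agreement == 1.0
        assert rep.mismatches.empty

    def test_expert_vs_kmeans_disagree_only_below_severe_bound(
        self, patient_scores, corrected_values
    ):
        km = rm.kmeans_class_model(corrected_values, seed=0)
        rep = rm.compare_models(rm.datasets.expert_boundaries(), km,
                                patient_scores["score"])
        assert rep.agreement == pytest.approx(39 / 40)
        assert rep.mismatches["score"].tolist() == [pytest.approx(0.2935)]
        assert np.abs(rep.boundary_deltas).max() < 0.03

    def test_different_k_rejected(self):
        a = rm.datasets.expert_boundaries()
        b = rm.ClassModel(((0.0, 0.5), (0.6, 1.0)), labels=("x", "y"))
        with pytest.raises(ValueError, match="same number"):
            rm.compare_models(a, b, [0.5])


class TestClassModel:
    def test_json_round_trip(self, tmp_path):
        model = rm.datasets.kmeans_boundaries()
        path = tmp_path / "m.json"
        rm.io.write_class_model(model, path)
        assert rm.io.read_class_model(path) == model

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(rm.ClassModelError, match="overlap"):
            rm.ClassModel(((0.0, 0.5), (0.5, 1.0)), labels=("x", "y"))

    def test_inverted_interval_rejected(self):
        with pytest.raises(rm.ClassModelError, match="inverted"):
            rm.ClassModel(((0.5, 0.1),), labels=("x",))
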