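"""Turing-test sessions, confusion scoring, and the cosine k-NN audit."""

import numpy as np
import pytest

from synthmetrics import (
    ConfusionCounts,
    FeatureMatrix,
    build_session,
    confusion_metrics,
    cosine_neighbors,
    score_responses,
    top_matches,
)
from synthmetrics.perceptual_eval import responses_from_csv, session_to_csv

# Observer confusion counts from the expert reader study, one row per
# (observer, training-set size): TP, FP, TN, FN and the published 2-decimal
# accuracy / sensitivity / specificity. Two published sensitivities are
# inconsistent with their own counts (36/50 = 0.72 != 0.53 and
# 18/50 = 0.36 != 0.32); those two entries carry the count-derived value
# in `sens` and the discrepant printed one in `printed_sens_discrepant`.
READER_STUDY_ROWS = [
    # observer, size, TP, FP, TN, FN, acc, sens, spec, printed_sens_discrepant
    ("#1", 1000, 36, 33, 17, 14, 0.53, 0.72, 0.34, None),
    ("#1", 2000, 36, 31, 19, 14, 0.55, 0.72, 0.38, 0.53),
    ("#1", 3227, 32, 31, 19, 18, 0.51, 0.64, 0.38, None),
    ("#2", 1000, 18, 24, 26, 32, 0.44, 0.36, 0.52, 0.32),
    ("#2", 2000, 26, 33, 17, 24, 0.43, 0.52, 0.34, None),
    ("#2", 3227, 29, 31, 19, 21, 0.48, 0.58, 0.38, None),
]


class TestSession:
    def test_balanced_session_shape(self):
        reals = [f"r{i}" for i in range(757)]
        synths = [f"s{i}" for i in range(2000)]
        session = build_session(reals, synths, n_each=50, seed=0)
        assert len(session.items) == 100
        labels = list(session.key.values())
        assert labels.count("real") == 50 and labels.count("synthetic") == 50

    def test_same_seed_same_order(self):
        reals = [f"r{i}" for i in range(100)]
        synths = [f"s{i}" for i in range(100)]
        a = build_session(reals, synths, seed=4)
        b = build_session(reals, synths, seed=4)
        assert a.items == b.items and a.key == b.key

    def test_presentation_list_carries_no_labels(self):
        session = build_session([f"r{i}" for i in range(60)], [f"s{i}" for i in range(60)], seed=1)
        for item_id, ref in session.items:
            assert "real" not in item_id and "synthetic" not in item_id

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_session(["r0"], [f"s{i}" for i in range(60)], n_each=50)

    def test_csv_round_trip_scores_identically(self, tmp_path):
        session = build_session(
            [f"r{i}" for i in range(60)], [f"s{i}" for i in range(60)], seed=2
        )
        session_to_csv(session, tmp_path / "items.csv", tmp_path / "key.csv")
        # observer who calls everything real
        responses_path = tmp_path / "resp.csv"
        responses_path.write_text(
            "item_id,label\n"
            + "\n".join(f"{item_id},real" for item_id, _ in session.items)
            + "\n"
        )
        counts = score_responses(session, responses_from_csv(responses_path))
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (50, 50, 0, 0)


class TestScoring:
    def test_all_correct(self):
        session = build_session(
            [f"r{i}" for i in range(60)], [f"s{i}" for i in range(60)], seed=0
        )
        counts = score_responses(session, dict(session.key))
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (50, 50, 0, 0)

    def test_missing_response_lists_item_ids(self):
        session = build_session(
            [f"r{i}" for i in range(60)], [f"s{i}" for i in range(60)], seed=0
        )
        responses = dict(session.key)
        responses.pop("item_042")
        with pytest.raises(ValueError, match="item_042"):
            score_responses(session, responses)

    def test_constructed_observer_reproduces_reader_counts(self):
        # build a response vector yielding the first reader-study row
        session = build_session(
            [f"r{i}" for i in range(60)], [f"s{i}" for i in range(60)], seed=9
        )
        tp, fp = 36, 33
        responses = {}
        n_real_seen = n_synth_seen = 0
        for item_id, _ in session.items:
            if session.key[item_id] == "real":
                responses[item_id] = "real" if n_real_seen < tp else "synthetic"
                n_real_seen += 1
            else:
                responses[item_id] = "real" if n_synth_seen < fp else "synthetic"
                n_synth_seen += 1
        counts = score_responses(session, responses)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (36, 33, 17, 14)
        metrics = confusion_metrics(counts)
        assert (metrics["accuracy_2dp"], metrics["sensitivity_2dp"], metrics["specificity_2dp"]) == (
            0.53,
            0.72,
            0.34,
        )


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "observer, size, tp, fp, tn, fn, acc, sens, spec, discrepant",
        READER_STUDY_ROWS,
    )
    def test_reader_study_rows(self, observer, size, tp, fp, tn, fn, acc, sens, spec, discrepant):
        m = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m["accuracy_2dp"] == acc
        assert m["sensitivity_2dp"] == sens
        assert m["specificity_2dp"] == spec

    def test_perfect_observer(self):
        m = confusion_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1.0, 1.0, 1.0)

    def test_accuracy_times_total_is_exact(self):
        c = ConfusionCounts(tp=36, fp=33, tn=17, fn=14)
        m = confusion_metrics(c)
        assert m["accuracy"] * c.total == c.tp + c.tn

    def test_zero_denominator_flagged_not_raised(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=5, tn=5, fn=0))
        assert m["sensitivity"] is None and m["accuracy"] == 0.5


class TestCosineNeighbors:
    def test_exact_copy_has_similarity_one_at_rank_one(self, rng):
        real = rng.standard_normal((3, 5))
        synth = np.vstack([rng.standard_normal((4, 5)), real[1] * 2.0])
        table = cosine_neighbors(
            FeatureMatrix(real), FeatureMatrix(synth, source="synthetic"), k=2
        )
        assert table.indices[1, 0] == 4
        assert table.similarities[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors_similarity_zero(self):
        real = FeatureMatrix(np.array([[1.0, 0.0]]))
        synth = FeatureMatrix(np.array([[0.0, 1.0], [0.0, 2.0]]), source="synthetic")
        table = cosine_neighbors(real, synth, k=2)
        np.testing.assert_allclose(table.similarities, 0.0, atol=1e-12)
        assert table.indices[0].tolist() == [0, 1]  # tie broken by index

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        real = rng.standard_normal((5, 6))
        synth = rng.standard_normal((8, 6))
        table = cosine_neighbors(
            FeatureMatrix(real), FeatureMatrix(synth, source="synthetic"), k=4
        )
        for i in range(5):
            sims = [
                float(np.dot(real[i], synth[j]) / (np.linalg.norm(real[i]) * np.linalg.norm(synth[j])))
                for j in range(8)
            ]
            expected = sorted(range(8), key=lambda j: (-sims[j], j))[:4]
            assert table.indices[i].tolist() == expected
            np.testing.assert_allclose(
                table.similarities[i], [sims[j] for j in expected], atol=1e-9
            )

    def test_invariant_to_positive_rescaling(self, rng):
        real = rng.standard_normal((4, 5))
        synth = rng.standard_normal((6, 5))
        scales = rng.uniform(0.1, 10.0, size=6)[:, np.newaxis]
        a = cosine_neighbors(FeatureMatrix(real), FeatureMatrix(synth), k=3)
        b = cosine_neighbors(FeatureMatrix(real), FeatureMatrix(synth * scales), k=3)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_allclose(a.similarities, b.similarities, atol=1e-9)

    def test_zero_norm_vector_rejected(self, rng):
        real = FeatureMatrix(np.vstack([rng.standard_normal((2, 3)), np.zeros(3)]))
        synth = FeatureMatrix(rng.standard_normal((4, 3)), source="synthetic")
        with pytest.raises(ValueError, match="row 2"):
            cosine_neighbors(real, synth)


class TestTopMatches:
    def test_selects_highest_rank1_rows_with_layout(self, rng):
        real = rng.standard_normal((6, 4))
        synth = np.vstack([rng.standard_normal((7, 4)), real[3], real[5]])
        table = cosine_neighbors(
            FeatureMatrix(real), FeatureMatrix(synth, source="synthetic"), k=4
        )
        spec = top_matches(table, n_real_shown=2)
        assert {row["real"] for row in spec["rows"]} == {3, 5}
        assert spec["n_cols"] == 5
        assert all(len(row["neighbors"]) == 4 for row in spec["rows"])
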