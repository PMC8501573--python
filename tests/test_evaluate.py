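"""Benchmark metrics: top-host ties, level accuracy, AUC/AUPR/F1 oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phirank.evaluate import (
    LEVELS,
    EvalReport,
    InteractionTruth,
    TaxonomyTable,
    accuracy_at_level,
    best_f1_threshold,
    evaluate_benchmark,
    pr_aupr,
    predict_hosts,
    roc_auc,
)
from phirank.scoring import ScoreMatrix

from _oracles import brute_auc, brute_aupr, brute_best_f1


def matrix(rows, viruses=None, hosts=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    viruses = viruses or tuple(f"v{i+1}" for i in range(rows.shape[0]))
    hosts = hosts or tuple(f"h{j+1}" for j in range(rows.shape[1]))
    return ScoreMatrix(tuple(viruses), tuple(hosts), rows)


def lineage(**kw):
    return tuple(kw.get(level) for level in LEVELS)


class TestPredictHosts:
    def test_all_equal_maximum_hosts_returned(self):
        preds = predict_hosts(matrix([[0.2, 0.9, 0.9]]))
        assert preds["v1"] == (frozenset({"h2", "h3"}), 0.9)

    def test_degenerate_all_zero_row_returns_every_host(self):
        preds = predict_hosts(matrix([[0.0, 0.0, 0.0]]))
        assert preds["v1"] == (frozenset({"h1", "h2", "h3"}), 0.0)

    def test_single_host(self):
        assert predict_hosts(matrix([[0.5]]))["v1"] == (frozenset({"h1"}), 0.5)


class TestAccuracyAtLevel:
    taxonomy = TaxonomyTable(
        {
            "h1": ("s1", "g1", "f1", "o1", "c1", "p1"),
            "h2": ("s2", "g1", "f1", "o1", "c1", "p1"),
            "h3": ("s3", "g2", "f2", "o2", "c2", "p2"),
        }
    )

    def test_genus_match_counts(self):
        truth = InteractionTruth({("v1", "h1")})
        preds = {"v1": (frozenset({"h2"}), 0.9)}
        assert accuracy_at_level(preds, truth, self.taxonomy, "genus") == 100.0
        assert accuracy_at_level(preds, truth, self.taxonomy, "species") == 0.0

    def test_partial_accuracy(self):
        truth = InteractionTruth({("v1", "h1"), ("v2", "h3")})
        preds = {
            "v1": (frozenset({"h1"}), 0.9),
            "v2": (frozenset({"h1"}), 0.9),
        }
        assert accuracy_at_level(preds, truth, self.taxonomy, "species") == 50.0

    def test_true_host_inside_tie_set_counts_correct(self):
        truth = InteractionTruth({("v1", "h3")})
        preds = {"v1": (frozenset({"h2", "h3"}), 0.9)}
        assert (
            accuracy_at_level(preds, truth, self.taxonomy, "species") == 100.0
        )

    def test_missing_lineage_is_nonmatch_not_crash(self):
        taxonomy = TaxonomyTable(
            {
                "h1": ("s1", None, "f1", "o1", "c1", "p1"),
                "h2": ("s2", None, "f1", "o1", "c1", "p1"),
            }
        )
        truth = InteractionTruth({("v1", "h1")})
        preds = {"v1": (frozenset({"h2"}), 0.9)}
        assert accuracy_at_level(preds, truth, taxonomy, "genus") == 0.0
        assert accuracy_at_level(preds, truth, taxonomy, "family") == 100.0

    def test_errors(self):
        truth = InteractionTruth({("v1", "h1")})
        preds = {"v1": (frozenset({"h1"}), 0.9)}
        with pytest.raises(ValueError, match="level"):
            accuracy_at_level(preds, truth, self.taxonomy, "kingdom")
        with pytest.raises(ValueError, match="no known host"):
            accuracy_at_level(
                {"vX": (frozenset({"h1"}), 0.9)}, truth, self.taxonomy, "genus"
            )

    def test_monotone_from_species_to_phylum(self):
        truth = InteractionTruth({("v1", "h1"), ("v2", "h3"), ("v3", "h2")})
        preds = {
            "v1": (frozenset({"h2"}), 0.9),
            "v2": (frozenset({"h1"}), 0.8),
            "v3": (frozenset({"h2"}), 0.7),
        }
        accs = [
            accuracy_at_level(preds, truth, self.taxonomy, level)
            for level in LEVELS
        ]
        assert accs == sorted(accs)


class TestRocAuc:
    def test_separated_and_identical(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_case(self):
        # positives {0.8, 0.4}, negatives {0.6, 0.2}: wins 3 of 4
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 50))
    def test_equals_pairwise_win_probability(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 10, size=n) / 10.0  # force ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        expected = brute_auc(
            scores[labels].tolist(), scores[~labels].tolist()
        )
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestAupr:
    def test_perfect_separation(self):
        assert pr_aupr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_equal_scores_give_prevalence(self):
        assert pr_aupr([0.5] * 4, [1, 0, 0, 0]) == pytest.approx(0.25)

    def test_three_point_hand_case(self):
        # thresholds 0.9/0.8/0.7 -> P,R = (1, .5), (.5, .5), (2/3, 1)
        got = pr_aupr([0.9, 0.8, 0.7], [1, 0, 1])
        assert got == pytest.approx(0.5 * 1 + 0.5 * 2 / 3, abs=1e-12)

    def test_matches_stepwise_oracle_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            scores = (rng.integers(0, 8, size=n) / 8.0).tolist()
            labels = rng.integers(0, 2, size=n).astype(bool)
            if not labels.any():
                labels[0] = True
            assert pr_aupr(scores, labels) == pytest.approx(
                brute_aupr(scores, labels.tolist()), abs=1e-12
            )

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            pr_aupr([0.5], [0])


class TestBestF1:
    def test_separated_classes_reach_one(self):
        thr, f1, precision, recall = best_f1_threshold(
            [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]
        )
        assert f1 == precision == recall == 1.0
        assert 0.2 < thr <= 0.8

    def test_hand_case(self):
        thr, f1, precision, recall = best_f1_threshold(
            [0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1]
        )
        assert thr == 0.6
        assert f1 == pytest.approx(6 / 7)
        assert precision == pytest.approx(3 / 4)
        assert recall == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            scores = (rng.integers(0, 10, size=n) / 10.0).tolist()
            labels = rng.integers(0, 2, size=n).astype(bool)
            if not labels.any():
                labels[0] = True
            got = best_f1_threshold(scores, labels)
            expected = brute_best_f1(scores, labels.tolist())
            assert got == pytest.approx(expected, abs=1e-12)


class TestEvaluateBenchmark:
    def test_full_report_on_tiny_benchmark(self, tmp_path):
        m = matrix([[0.9, 0.1], [0.2, 0.8]])
        truth = InteractionTruth({("v1", "h1"), ("v2", "h2")})
        taxonomy = TaxonomyTable(
            {
                "h1": ("s1", "g1", "f1", "o1", "c1", "p1"),
                "h2": ("s2", "g2", "f2", "o2", "c2", "p2"),
            }
        )
        report = evaluate_benchmark(m, truth, taxonomy)
        assert report.auc == 1.0
        assert report.aupr == 1.0
        assert report.f1 == 1.0
        assert report.specificity == 1.0
        assert report.accuracy_by_level["species"] == 100.0
        # JSON round-trips through a file
        path = tmp_path / "report.json"
        report.to_json(path)
        assert "accuracy_by_level" in path.read_text()

    def test_truth_must_be_covered_by_matrix(self):
        m = matrix([[0.9]])
        truth = InteractionTruth({("v1", "hZ")})
        with pytest.raises(ValueError, match="not covered"):
            evaluate_benchmark(m, truth, TaxonomyTable({}))


def test_truth_and_taxonomy_tsv_round_trip(tmp_path):
    truth = InteractionTruth({("v1", "h1"), ("v2", "h2")})
    tpath = tmp_path / "truth.tsv"
    truth.to_tsv(tpath)
    assert InteractionTruth.from_tsv(tpath) == truth

    taxonomy = TaxonomyTable(
        {"h1": ("s1", None, "f1", "o1", "c1", "p1")}
    )
    xpath = tmp_path / "tax.tsv"
    taxonomy.to_tsv(xpath)
    back = TaxonomyTable.from_tsv(xpath)
    assert back.label("h1", "species") == "s1"
    assert back.label("h1", "genus") is None
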