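"""Annotator reconciliation, the metric battery, and preference pairs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourms import agreement as ag
from fourms import extraction as ex
from fourms import synthdata as sd
from fourms.extraction import MClass, M_CLASSES

import _oracles as orc


def annotation_set(annotator_id, data):
    """data: {message_id: {class: [phrases]}} with missing classes empty."""
    records = {
        mid: {c: list(classes.get(c, [])) for c in M_CLASSES}
        for mid, classes in data.items()
    }
    return ag.AnnotationSet(annotator_id, records)


class TestDiffAndReconcile:
    def test_identical_sets_have_no_differences(self):
        a = annotation_set("A", {"m1": {MClass.MEDICATION: ["lasix dose"]}})
        b = annotation_set("B", {"m1": {MClass.MEDICATION: ["lasix dose"]}})
        report = ag.diff_annotations(a, b)
        assert sum(report.per_class.values()) == 0

    def test_one_sided_extraction_is_one_difference(self):
        a = annotation_set("A", {"m1": {MClass.MENTATION: ["symbolic disfunction"]}})
        b = annotation_set("B", {"m1": {}})
        report = ag.diff_annotations(a, b)
        assert report.per_class[MClass.MENTATION] == 1
        assert report.items[0].side == "A"

    def test_typo_variants_match_as_same_phrase(self):
        a = annotation_set("A", {"m1": {MClass.MENTATION: ["symbolic disfunction"]}})
        b = annotation_set("B", {"m1": {MClass.MENTATION: ["symbolic dysfunction"]}})
        assert sum(ag.diff_annotations(a, b).per_class.values()) == 0

    def test_accepted_difference_enters_gold_with_provenance(self):
        a = annotation_set("A", {"m1": {MClass.MENTATION: ["symbolic disfunction"]}})
        b = annotation_set("B", {"m1": {}})
        d = ag.diff_annotations(a, b).items[0]
        gold = ag.reconcile(a, b, {d.key(): "accept"})
        assert gold[0].counts[MClass.MENTATION] == 1
        assert gold[0].provenance[MClass.MENTATION] == ["A_only_accepted"]

    def test_all_rejected_gives_intersection(self):
        a = annotation_set("A", {"m1": {MClass.MOBILITY: ["fall risk", "bed bound"]}})
        b = annotation_set("B", {"m1": {MClass.MOBILITY: ["fall risk"]}})
        d = ag.diff_annotations(a, b).items[0]
        gold = ag.reconcile(a, b, {d.key(): "reject"})
        assert gold[0].spans[MClass.MOBILITY] == ["fall risk"]

    def test_unadjudicated_difference_is_fatal_and_lists_items(self):
        a = annotation_set("A", {"m1": {MClass.MOBILITY: ["walker needed"]}})
        b = annotation_set("B", {"m1": {}})
        with pytest.raises(ValueError, match="walker needed"):
            ag.reconcile(a, b, {})

    def test_no_differences_gold_equals_either_annotator(self):
        data = {"m1": {MClass.MEDICATION: ["insulin held"]},
                "m2": {}}
        gold = ag.reconcile(annotation_set("A", data), annotation_set("B", data), {})
        assert gold[0].spans[MClass.MEDICATION] == ["insulin held"]
        assert gold[1].counts == {c: 0 for c in M_CLASSES}

    def test_planted_disagreement_rate_within_binomial_bounds(self, small_corpus):
        rate = 0.1
        a, b, _ = sd.simulate_annotators(small_corpus.truth, rate, seed=3)
        m = sum(len(v) for v in small_corpus.truth.message_spans.values())
        observed = sum(ag.diff_annotations(a, b).per_class.values())
        p = 2 * rate / (1 + rate)  # per-span difference probability (no both-drop)
        sigma = (m * p * (1 - p)) ** 0.5
        assert abs(observed - m * p) < 4 * sigma

    def test_annotation_file_round_trip(self, tmp_path, small_corpus):
        a, b, _ = sd.simulate_annotators(small_corpus.truth, 0.1, seed=3)
        ag.write_annotations([a, b], tmp_path / "ann.csv")
        loaded = ag.load_annotations(tmp_path / "ann.csv")
        assert loaded["A"].records == a.records
        assert loaded["B"].records == b.records


class TestCohenKappa:
    def test_symmetric_table_frozen_value(self):
        # 2x2 table [[40,10],[10,40]]: p_o=0.8, p_e=0.5 -> kappa=0.6
        x = [1] * 50 + [0] * 50
        y = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        assert ag.cohen_kappa(x, y) == pytest.approx(0.6, abs=1e-12)

    def test_perfect_agreement_with_both_labels(self):
        assert ag.cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert abs(ag.cohen_kappa(x, y)) < 0.05

    def test_degenerate_all_same_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert ag.cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            ag.cohen_kappa([0, 1], [0])

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=20),
           st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_kappa_symmetry(self, x, data):
        y = data.draw(st.lists(st.integers(0, 1), min_size=len(x), max_size=len(x)))
        assert ag.cohen_kappa(x, y) == pytest.approx(ag.cohen_kappa(y, x), abs=1e-12)


class TestMetricBattery:
    def test_perfect_prediction(self):
        gold = [1, 0, 1, 1, 0]
        m = ag.binary_metrics(gold, gold, scores=gold)
        assert (m["recall"], m["f1"], m["kappa"], m["auc"]) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_prediction(self):
        m = ag.binary_metrics([0, 0, 0, 0], [1, 1, 0, 0])
        assert m["recall"] == 0.0 and m["f1"] == 0.0

    def test_auc_missing_when_gold_single_class(self):
        m = ag.binary_metrics([0, 1, 0], [1, 1, 1], scores=[0, 1, 0])
        assert m["auc"] is None and m["recall"] is not None

    def test_count_metrics_identity_and_shift(self):
        c = [0, 1, 2, 3, 5]
        m = ag.count_metrics(c, c)
        assert m["spearman_rho"] == pytest.approx(1.0) and m["kappa_binned"] == 1.0
        assert m["mae"] == 0.0
        shifted = ag.count_metrics([v + 1 for v in c], c)
        assert shifted["mae"] == 1.0

    def test_default_bins_pool_three_plus(self):
        assert list(ag.bin_counts([0, 1, 2, 3, 7])) == [0, 1, 2, 3, 3]

    @pytest.mark.parametrize("seed", range(10))
    def test_battery_equals_bruteforce_oracles_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        pred = rng.integers(0, 2, n).tolist()
        gold = rng.integers(0, 2, n).tolist()
        scores = rng.integers(0, 4, n).tolist()
        m = ag.binary_metrics(pred, gold, scores=scores)
        assert m["recall"] == pytest.approx(orc.oracle_recall(pred, gold), abs=1e-9) or m["recall"] is None
        assert m["kappa"] == pytest.approx(orc.oracle_kappa(pred, gold), abs=1e-9)
        if m["auc"] is not None:
            assert m["auc"] == pytest.approx(orc.oracle_auc(scores, gold), abs=1e-9)
        pc = rng.integers(0, 5, n).tolist()
        gc = rng.integers(0, 5, n).tolist()
        cm = ag.count_metrics(pc, gc)
        assert cm["mae"] == pytest.approx(orc.oracle_mae(pc, gc), abs=1e-9)
        assert cm["kappa_binned"] == pytest.approx(
            orc.oracle_binned_kappa(pc, gc, ag.DEFAULT_BINS), abs=1e-9)
        rho = orc.oracle_spearman(pc, gc)
        if cm["spearman_rho"] is not None and rho is not None:
            assert cm["spearman_rho"] == pytest.approx(rho, abs=1e-9)


class TestEvaluate:
    def _results_from_gold(self, gold):
        return [
            ex.ExtractionResult(g.message_id, {c: list(g.spans[c]) for c in M_CLASSES})
            for g in gold
        ]

    def test_gold_vs_itself_is_perfect_and_passes_gate(self, small_corpus):
        gold = small_corpus.truth.gold_records()
        report = ag.evaluate(self._results_from_gold(gold), gold)
        for c in M_CLASSES:
            assert report.per_class[c]["kappa"] == 1.0
            assert report.per_class[c]["mae"] == 0.0
        assert report.overall_kappa == 1.0 and report.passes_gate

    def test_gate_thresholds_respected(self, small_corpus):
        gold = small_corpus.truth.gold_records()
        report = ag.evaluate(self._results_from_gold(gold), gold, kappa_gate=0.60)
        assert report.kappa_gate == 0.60
        assert all(report.per_class_gate.values())

    def test_evaluate_invariant_to_result_order(self, small_corpus):
        gold = small_corpus.truth.gold_records()
        results = self._results_from_gold(gold)
        r1 = ag.evaluate(results, gold)
        r2 = ag.evaluate(list(reversed(results)), gold)
        assert r1.to_dict() == r2.to_dict()

    def test_missing_result_is_fatal(self, small_corpus):
        gold = small_corpus.truth.gold_records()
        with pytest.raises(ValueError):
            ag.evaluate(self._results_from_gold(gold)[:-1], gold)

    def test_planted_error_rates_recover_analytic_kappa(self):
        # moderate n: check convergence direction at generous tolerance; the
        # tight check at n=5000 lives in the acceptance suite
        synth = sd.generate_corpus(sd.GeneratorConfig(n_messages=2000, seed=21))
        lex = synth.lexicon
        results = ex.run_extractor(synth.messages, ex.LexiconExtractor(lex))
        results = ex.validate_all(results, synth.messages)
        gold = synth.truth.gold_records()
        noisy = sd.corrupt_results(results, synth.vocabulary, seed=22,
                                   fp_rate=0.1, fn_rate=0.2)
        report = ag.evaluate(noisy, gold)
        for c in M_CLASSES:
            prev = float(np.mean([g.binary[c] for g in gold]))
            expected = sd.analytic_kappa(prev, 0.1, 0.2)
            assert report.per_class[c]["kappa"] == pytest.approx(expected, abs=0.08)


class TestPreferencePairs:
    def _setup(self, small_corpus):
        gold = small_corpus.truth.gold_records()
        results = [
            ex.ExtractionResult(g.message_id, {c: list(g.spans[c]) for c in M_CLASSES})
            for g in gold
        ]
        return gold, results

    def test_exact_agreement_emits_no_pairs(self, small_corpus):
        gold, results = self._setup(small_corpus)
        pairs = ag.build_preference_pairs(results, gold, small_corpus.messages, "Q: {text}")
        assert pairs == []

    def test_spurious_span_produces_one_pair_with_correct_sides(self, small_corpus):
        gold, results = self._setup(small_corpus)
        results[0].spans[MClass.MEDICATION].append("ghost span")
        pairs = ag.build_preference_pairs(results, gold, small_corpus.messages, "Q: {text}")
        assert len(pairs) == 1
        assert "ghost span" in pairs[0].rejected
        assert "ghost span" not in pairs[0].chosen
        assert pairs[0].chosen != pairs[0].rejected

    def test_planted_discrepancy_count_is_exact(self, small_corpus):
        gold, results = self._setup(small_corpus)
        discrepant = [r.message_id for r in results[::3]]
        noisy = sd.corrupt_results(results, small_corpus.vocabulary, seed=5,
                                   message_ids=discrepant)
        pairs = ag.build_preference_pairs(noisy, gold, small_corpus.messages, "Q: {text}")
        assert len(pairs) == len(discrepant)
        assert {p.message_id for p in pairs} == set(discrepant)

    def test_split_is_reproducible_and_leak_free(self, small_corpus):
        gold, results = self._setup(small_corpus)
        noisy = sd.corrupt_results(results, small_corpus.vocabulary, seed=5,
                                   message_ids=[r.message_id for r in results[:100]])
        pairs = ag.build_preference_pairs(noisy, gold, small_corpus.messages, "Q: {text}")
        train, val = ag.split_pairs(pairs, 20, seed=9)
        train2, val2 = ag.split_pairs(pairs, 20, seed=9)
        assert (train, val) == (train2, val2)
        assert len(val) == 20 and len(train) == len(pairs) - 20
        assert {p.message_id for p in train}.isdisjoint({p.message_id for p in val})
        train3, val3 = ag.split_pairs(pairs, 20, seed=10)
        assert val3 != val

    def test_oversized_validation_request_fatal(self, small_corpus):
        gold, results = self._setup(small_corpus)
        results[0].spans[MClass.MOBILITY].append("extra")
        pairs = ag.build_preference_pairs(results, gold, small_corpus.messages, "Q: {text}")
        with pytest.raises(ValueError):
            ag.split_pairs(pairs, len(pairs), seed=1)

    def test_pairs_file_round_trip(self, tmp_path, small_corpus):
        gold, results = self._setup(small_corpus)
        results[0].spans[MClass.MOBILITY].append("extra")
        pairs = ag.build_preference_pairs(results, gold, small_corpus.messages, "Q: {text}")
        ag.write_pairs(pairs, tmp_path / "pairs.jsonl")
        assert ag.load_pairs(tmp_path / "pairs.jsonl") == pairs
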