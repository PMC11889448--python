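"""Scoring: component P/R/F1, validity rate, architecture comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlbeacon import evaluation, extraction, synth
from nlbeacon.evaluation import (
    EvalReport,
    GoldExample,
    compare_architectures,
    evaluate,
    load_gold_set,
    save_gold_set,
    score_example,
)
from nlbeacon.extraction import (
    COMPONENTS,
    ExtractionState,
    ExtractorBackend,
    ExtractResult,
    ScopeCandidate,
)
from nlbeacon.model import FilterClause, OntologyTerm


class PerfectBackend(ExtractorBackend):
    """Returns each example's gold components (set per example)."""

    deterministic = True

    def __init__(self):
        self.gold = None

    def set_gold(self, gold: dict):
        self.gold = gold

    def extract(self, task, utterance, context) -> ExtractResult:
        from nlbeacon.ontology import RsidTable

        g = self.gold
        if task == "scope":
            s = g.get("scope")
            cand = (
                ScopeCandidate(**s) if s else None
            )
            return ExtractResult(cand, 1)
        if task == "granularity":
            return ExtractResult(g.get("granularity"), 1)
        if task == "variants":
            table = RsidTable.packaged()
            return ExtractResult(
                [table.entries[r] for r in g.get("variants", [])], 1
            )
        return ExtractResult(
            [
                FilterClause(OntologyTerm(f["curie"]), f.get("applies_to"))
                for f in g.get("filters", [])
            ],
            1,
        )


class EmptyBackend(ExtractorBackend):
    deterministic = True

    def extract(self, task, utterance, context) -> ExtractResult:
        return ExtractResult(None, 1)


class TestScoreExample:
    def test_exact_match_counts_only_tp(self, rule_backend):
        gold = synth.generate_gold_set(6, seed=1)[0]
        state = extraction.extract_parallel(
            gold.utterance, rule_backend, ExtractionState()
        )
        counts = score_example(state, gold)
        for comp in COMPONENTS:
            assert counts[comp].fp == 0 and counts[comp].fn == 0

    def test_partial_filter_overlap_scores_half(self):
        predicted = ExtractionState(
            entity_type="individuals",
            filters=[
                FilterClause(OntologyTerm("TERM:A"), "individuals"),
                FilterClause(OntologyTerm("TERM:B"), "individuals"),
            ],
        )
        gold = GoldExample(
            utterance="",
            gold={
                "scope": None,
                "granularity": None,
                "variants": [],
                "filters": [
                    {"curie": "TERM:A", "applies_to": "individuals"},
                    {"curie": "TERM:C", "applies_to": "individuals"},
                ],
            },
        )
        c = score_example(predicted, gold)["filters"]
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)
        # P = R = F1 = 0.5 for these counts
        p = c.tp / (c.tp + c.fp)
        r = c.tp / (c.tp + c.fn)
        assert p == r == 0.5

    def test_empty_prediction_nonempty_gold_is_pure_fn(self):
        gold = GoldExample(
            utterance="",
            gold={
                "scope": {"collection_scope": "cohort", "entity_type": "individuals"},
                "granularity": "count",
                "variants": ["rs356181"],
                "filters": [{"curie": "TERM:A", "applies_to": "individuals"}],
            },
        )
        counts = score_example(ExtractionState(), gold)
        for comp in COMPONENTS:
            assert counts[comp].tp == 0 and counts[comp].fp == 0
            assert counts[comp].fn == 1

    def test_wrong_single_label_counts_fp_and_fn(self):
        predicted = ExtractionState(granularity="boolean")
        gold = GoldExample(
            utterance="", gold={"granularity": "count", "scope": None}
        )
        c = score_example(predicted, gold)["granularity"]
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)


class TestEvaluate:
    def test_perfect_backend_scores_one(self):
        # examples with every component populated; the backend echoes gold
        gold = [
            ex for ex in synth.generate_gold_set(18, seed=2)
            if "full_variant" in ex.tags
        ]
        assert gold
        backend = PerfectBackend()
        for ex in gold:  # one at a time: the echo backend is per-example
            backend.set_gold(ex.gold)
            rep = evaluate([ex], backend, "parallel")
            assert rep.average_f1 == 1.0
            assert rep.validity_rate == 1.0

    def test_empty_backend_scores_zero(self):
        gold = synth.generate_gold_set(12, seed=3)
        rep = evaluate(gold, EmptyBackend(), "parallel")
        assert rep.average_f1 == 0.0
        assert rep.validity_rate == 0.0

    def test_empty_gold_set_rejected(self, rule_backend):
        with pytest.raises(ValueError):
            evaluate([], rule_backend)

    def test_report_equals_independent_naive_recount(self, rule_backend):
        gold = synth.generate_gold_set(20, seed=4)
        rep = evaluate(gold, rule_backend, "parallel")
        naive = naive_evaluate(gold, rule_backend)
        for comp in COMPONENTS:
            for metric in ("precision", "recall", "f1"):
                assert rep.per_component[comp][metric] == naive[comp][metric]
        assert rep.validity_rate == naive["validity_rate"]

    def test_metrics_permutation_invariant(self, rule_backend):
        gold = synth.generate_gold_set(15, seed=5)
        rep1 = evaluate(gold, rule_backend, "parallel")
        rep2 = evaluate(list(reversed(gold)), rule_backend, "parallel")
        assert rep1.per_component == rep2.per_component
        assert rep1.total_tokens == rep2.total_tokens

    @settings(max_examples=50, derandomize=True)
    @given(tp=st.integers(0, 5), fp=st.integers(0, 5), fn=st.integers(0, 5))
    def test_f1_bounds_and_zero_convention(self, tp, fp, fn):
        from nlbeacon.evaluation import Counts, _prf

        m = _prf(Counts(tp=tp, fp=fp, fn=fn))
        assert 0.0 <= m["f1"] <= 1.0
        if m["precision"] + m["recall"] == 0:
            assert m["f1"] == 0.0


class TestCompareArchitectures:
    def test_token_delta_positive_when_skips_occur(self, rule_backend):
        gold = [
            ex for ex in synth.generate_gold_set(30, seed=6)
            if "skip_eligible" in ex.tags
        ]
        paired = compare_architectures(gold, rule_backend)
        assert paired["token_delta"] > 0

    def test_equal_f1_without_failures_or_skips(self, rule_backend):
        gold = [
            ex for ex in synth.generate_gold_set(30, seed=7)
            if "skip_eligible" not in ex.tags
        ]
        paired = compare_architectures(gold, rule_backend)
        assert (
            paired["parallel"].per_component == paired["multistep"].per_component
        )

    def test_scope_failure_zeroes_multistep_only(self, failing_backend_factory):
        gold = synth.generate_gold_set(12, seed=8)
        backend = failing_backend_factory("scope")
        paired = compare_architectures(gold, backend)
        assert paired["multistep"].average_f1 == 0.0
        assert paired["parallel"].average_f1 > 0.0


class TestGoldSetIO:
    def test_jsonl_round_trip(self, tmp_path, rule_backend):
        gold = synth.generate_gold_set(10, seed=9)
        path = tmp_path / "gold.jsonl"
        save_gold_set(gold, path)
        loaded = load_gold_set(path)
        assert loaded == gold


# ---------------------------------------------------------------------------


def naive_evaluate(gold_set, backend) -> dict:
    """Straight-line recount, separate from the evaluation module's code."""
    tallies = {c: {"tp": 0, "fp": 0, "fn": 0} for c in COMPONENTS}
    valid = 0
    for ex in gold_set:
        state = extraction.extract_parallel(
            ex.utterance, backend, ExtractionState()
        )
        g = ex.gold

        gold_scope = g.get("scope")
        gold_label = (
            (gold_scope.get("collection_scope"), gold_scope.get("entity_type"))
            if gold_scope
            else None
        )
        pred_label = (
            None
            if state.entity_type is None and state.collection_scope is None
            else (state.collection_scope, state.entity_type)
        )
        _tally_label(tallies["scope"], pred_label, gold_label)
        _tally_label(tallies["granularity"], state.granularity, g.get("granularity"))

        pred_vars = set()
        for v in state.variants:
            pred_vars.add(("rsid", v.rsid) if v.rsid else (
                "coords", v.reference_name, v.start, v.reference_bases,
                v.alternate_bases))
        gold_vars = {
            ("rsid", v) if isinstance(v, str) else ("coords", *v)
            for v in g.get("variants", [])
        }
        _tally_set(tallies["variants"], pred_vars, gold_vars)

        pred_filters = {
            (f.term.curie, f.applies_to or state.entity_type) for f in state.filters
        }
        gold_entity = (gold_scope or {}).get("entity_type")
        gold_filters = {
            (f["curie"], f.get("applies_to") or gold_entity)
            for f in g.get("filters", [])
        }
        _tally_set(tallies["filters"], pred_filters, gold_filters)

        built = extraction.build_query(state, default_collection="DEFAULT")
        from nlbeacon.model import BeaconQuery, validate_query

        if isinstance(built, BeaconQuery) and validate_query(built).valid:
            valid += 1

    out = {}
    for comp, t in tallies.items():
        p = t["tp"] / (t["tp"] + t["fp"]) if t["tp"] + t["fp"] else 0.0
        r = t["tp"] / (t["tp"] + t["fn"]) if t["tp"] + t["fn"] else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        out[comp] = {"precision": p, "recall": r, "f1": f1}
    out["validity_rate"] = valid / len(gold_set)
    return out


def _tally_label(t, pred, gold):
    if gold is None and pred is None:
        return
    if gold is None:
        t["fp"] += 1
    elif pred is None:
        t["fn"] += 1
    elif pred == gold:
        t["tp"] += 1
    else:
        t["fp"] += 1
        t["fn"] += 1


def _tally_set(t, pred, gold):
    t["tp"] += len(pred & gold)
    t["fp"] += len(pred - gold)
    t["fn"] += len(gold - pred)
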