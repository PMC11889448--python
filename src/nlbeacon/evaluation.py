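"""Extraction-quality scoring: per-component precision/recall/F1,
query-validity rate, and token consumption, per architecture.

Components are scored micro-averaged over a gold set:

* scope and granularity as single-label classification — scope is one
  joint label (collection_scope + entity_type), no partial credit;
* variants and filters as sets under canonical keys (rsid/coordinate key
  for variants, CURIE + applies_to for filters).

F1 = 2PR/(P+R), with the F1 = 0 convention when P + R = 0.  The headline
"average F1" is the arithmetic mean of the four component F1s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .extraction import (
    ARCHITECTURES,
    COMPONENTS,
    ExtractionState,
    ExtractorBackend,
    build_query,
)
from .model import BeaconQuery, validate_query


@dataclass
class GoldExample:
    """One utterance with its correct query components.

    ``gold`` holds: scope — {collection_scope, collection_id,
    entity_type} or None; granularity — value or None; variants — list
    of canonical keys (an rsid string or [chrom, start, ref, alt]);
    filters — list of {curie, applies_to}.
    """

    utterance: str
    gold: dict
    tags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"utterance": self.utterance, "gold": self.gold, "tags": self.tags},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "GoldExample":
        doc = json.loads(line)
        return cls(
            utterance=doc["utterance"],
            gold=doc["gold"],
            tags=list(doc.get("tags", [])),
        )


def load_gold_set(path: str | Path) -> list[GoldExample]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            out.append(GoldExample.from_json(line))
    return out


def save_gold_set(examples: list[GoldExample], path: str | Path) -> None:
    Path(path).write_text(
        "".join(e.to_json() + "\n" for e in examples), encoding="utf-8"
    )


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "Counts") -> "Counts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def _prf(c: Counts) -> dict[str, float]:
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return {"precision": p, "recall": r, "f1": f1}


@dataclass
class EvalReport:
    per_component: dict[str, dict[str, float]]
    average_f1: float
    validity_rate: float
    total_tokens: int
    n_examples: int

    def to_dict(self) -> dict:
        return {
            "per_component": self.per_component,
            "average_f1": self.average_f1,
            "validity_rate": self.validity_rate,
            "total_tokens": self.total_tokens,
            "n_examples": self.n_examples,
        }

    def to_table(self) -> str:
        lines = [f"{'component':<12} {'P':>6} {'R':>6} {'F1':>6}"]
        for comp in COMPONENTS:
            m = self.per_component[comp]
            lines.append(
                f"{comp:<12} {m['precision']:>6.3f} {m['recall']:>6.3f} "
                f"{m['f1']:>6.3f}"
            )
        lines.append(f"average F1     {self.average_f1:.3f}")
        lines.append(f"validity rate  {self.validity_rate:.3f}")
        lines.append(f"total tokens   {self.total_tokens}")
        lines.append(f"examples       {self.n_examples}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# scoring


def _predicted_scope_label(state: ExtractionState) -> tuple | None:
    if state.entity_type is None and state.collection_scope is None:
        return None
    return (state.collection_scope, state.entity_type)


def _gold_scope_label(gold: dict) -> tuple | None:
    scope = gold.get("scope")
    if not scope:
        return None
    return (scope.get("collection_scope"), scope.get("entity_type"))


def _variant_key(entry) -> tuple:
    if isinstance(entry, str):
        return ("rsid", entry)
    return ("coords", *entry)


def _predicted_variant_keys(state: ExtractionState) -> set:
    return {
        ("rsid", v.rsid)
        if v.rsid is not None
        else ("coords", v.reference_name, v.start, v.reference_bases, v.alternate_bases)
        for v in state.variants
    }


def _predicted_filter_keys(state: ExtractionState) -> set:
    entity = state.entity_type
    return {(f.term.curie, f.applies_to or entity) for f in state.filters}


def _gold_filter_keys(gold: dict) -> set:
    entity = (gold.get("scope") or {}).get("entity_type")
    return {
        (f["curie"], f.get("applies_to") or entity) for f in gold.get("filters", [])
    }


def _label_counts(predicted, gold) -> Counts:
    if gold is None and predicted is None:
        return Counts()
    if gold is None:
        return Counts(fp=1)
    if predicted is None:
        return Counts(fn=1)
    if predicted == gold:
        return Counts(tp=1)
    return Counts(fp=1, fn=1)


def _set_counts(predicted: set, gold: set) -> Counts:
    return Counts(
        tp=len(predicted & gold),
        fp=len(predicted - gold),
        fn=len(gold - predicted),
    )


def score_example(predicted: ExtractionState, gold: GoldExample) -> dict[str, Counts]:
    """Per-component TP/FP/FN for one example."""
    g = gold.gold
    gold_gran = g.get("granularity")
    return {
        "scope": _label_counts(_predicted_scope_label(predicted), _gold_scope_label(g)),
        "granularity": _label_counts(predicted.granularity, gold_gran),
        "variants": _set_counts(
            _predicted_variant_keys(predicted),
            {_variant_key(v) for v in g.get("variants", [])},
        ),
        "filters": _set_counts(_predicted_filter_keys(predicted), _gold_filter_keys(g)),
    }


def evaluate(
    gold_set: list[GoldExample],
    backend: ExtractorBackend,
    architecture: str = "parallel",
    default_collection: str = "DEFAULT",
) -> EvalReport:
    """Run one architecture over a gold set and micro-average the metrics."""
    if not gold_set:
        raise ValueError("gold set must be non-empty")
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    extractor = ARCHITECTURES[architecture]

    totals = {c: Counts() for c in COMPONENTS}
    valid = 0
    tokens = 0
    for example in gold_set:
        state = extractor(example.utterance, backend, ExtractionState())
        tokens += state.tokens_used
        for comp, counts in score_example(state, example).items():
            totals[comp] += counts
        built = build_query(state, default_collection=default_collection)
        if isinstance(built, BeaconQuery) and validate_query(built).valid:
            valid += 1

    per_component = {c: _prf(totals[c]) for c in COMPONENTS}
    return EvalReport(
        per_component=per_component,
        average_f1=sum(per_component[c]["f1"] for c in COMPONENTS) / len(COMPONENTS),
        validity_rate=valid / len(gold_set),
        total_tokens=tokens,
        n_examples=len(gold_set),
    )


def compare_architectures(
    gold_set: list[GoldExample], backend: ExtractorBackend
) -> dict:
    """Both architectures on identical inputs, plus the token difference."""
    parallel = evaluate(gold_set, backend, "parallel")
    multistep = evaluate(gold_set, backend, "multistep")
    return {
        "parallel": parallel,
        "multistep": multistep,
        "token_delta": parallel.total_tokens - multistep.total_tokens,
    }
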