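"""Natural-language → query-component extraction.

Four component extractors (scope, granularity, variants, filters) can be
orchestrated two ways:

* **parallel** — all four run independently on the same utterance and
  their results are merged; one failing extractor never blocks the other
  three, at the price of always paying all four invocation costs.
* **multi-step** — a fixed chain scope → granularity → variants →
  filters, each step seeing the prior steps' outputs; a failure aborts
  the chain (later components stay unset), and steps whose input makes
  them moot are skipped (the variants step is skipped when the utterance
  carries no genomic token), reducing token cost.

Backends are pluggable through :class:`ExtractorBackend`; the shipped
:class:`RuleBackend` is a deterministic keyword grammar over the packaged
lexicons so the whole pipeline is testable without any LLM service.  Its
token cost is the whitespace-token count of the rendered task input,
reported through the same field an LLM connector would use for provider
token counts.

Cohort data never flows through a backend: extraction sees only
utterances and prior extraction state.
"""

from __future__ import annotations

import json
import re
import uuid
from abc import ABC, abstractmethod
from dataclasses import asdict, dataclass, field

from .model import (
    BeaconQuery,
    FilterClause,
    OntologyTerm,
    VariantDescriptor,
)
from .ontology import (
    Lexicon,
    RsidTable,
    UnknownRsidError,
    resolve_rsid,
    scan_terms,
)

COMPONENTS = ("scope", "granularity", "variants", "filters")

#: Genomic-content detector used by the multi-step skip rule.
GENOMIC_TOKEN_RE = re.compile(
    r"rs\d+|chr(omosome)?\s*\w+|\bvariant|\bmutation", re.IGNORECASE
)


class ExtractionError(Exception):
    pass


class UnknownSessionError(KeyError):
    pass


@dataclass
class ExtractResult:
    """One backend invocation: a structured candidate plus its token cost."""

    candidate: object
    token_cost: int


class ExtractorBackend(ABC):
    """Contract for component extractors (rule-based or LLM connectors).

    ``extract`` receives the task name, the raw utterance, and a
    read-only context snapshot (prior session state; for the multi-step
    architecture, also the outputs of earlier chain steps).  It returns
    the candidate for that component — ``None`` / empty meaning "nothing
    found" — and the invocation's token cost.  Exceptions signal task
    failure and are handled by the orchestrators.
    """

    deterministic: bool = False

    @abstractmethod
    def extract(self, task: str, utterance: str, context: dict) -> ExtractResult:
        ...


@dataclass
class ScopeCandidate:
    collection_scope: str | None = None
    collection_id: str | None = None
    entity_type: str | None = None
    has_genomic: bool = False

    def is_empty(self) -> bool:
        return (
            self.collection_scope is None
            and self.collection_id is None
            and self.entity_type is None
        )


@dataclass
class ExtractionState:
    """Accumulated query components plus per-component status and costs.

    This is the conversation-history object: the variants, filters,
    chosen scope and granularity of a session, carried across turns so
    users can build on previous queries.
    """

    collection_scope: str | None = None
    collection_id: str | None = None
    entity_type: str | None = None
    granularity: str | None = None
    variants: list[VariantDescriptor] = field(default_factory=list)
    filters: list[FilterClause] = field(default_factory=list)
    component_status: dict[str, str] = field(
        default_factory=lambda: {c: "unset" for c in COMPONENTS}
    )
    tokens_used: int = 0
    transcript: list[tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "ExtractionState":
        return ExtractionState(
            collection_scope=self.collection_scope,
            collection_id=self.collection_id,
            entity_type=self.entity_type,
            granularity=self.granularity,
            variants=list(self.variants),
            filters=list(self.filters),
            component_status=dict(self.component_status),
            tokens_used=self.tokens_used,
            transcript=list(self.transcript),
        )

    def snapshot(self) -> dict:
        """Read-only context given to backends: components only, no data."""
        return {
            "collection_scope": self.collection_scope,
            "collection_id": self.collection_id,
            "entity_type": self.entity_type,
            "granularity": self.granularity,
            "variants": [v.rsid or v.key() for v in self.variants],
            "filters": [f.key() for f in self.filters],
        }

    # -- persistence (CLI sessions, transcript export) ------------------

    def to_json(self) -> str:
        doc = {
            "collection_scope": self.collection_scope,
            "collection_id": self.collection_id,
            "entity_type": self.entity_type,
            "granularity": self.granularity,
            "variants": [asdict(v) for v in self.variants],
            "filters": [
                {
                    "curie": f.term.curie,
                    "label": f.term.label,
                    "applies_to": f.applies_to,
                }
                for f in self.filters
            ],
            "component_status": self.component_status,
            "tokens_used": self.tokens_used,
            "transcript": [list(t) for t in self.transcript],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExtractionState":
        doc = json.loads(text)
        return cls(
            collection_scope=doc["collection_scope"],
            collection_id=doc["collection_id"],
            entity_type=doc["entity_type"],
            granularity=doc["granularity"],
            variants=[VariantDescriptor(**v) for v in doc["variants"]],
            filters=[
                FilterClause(
                    OntologyTerm(f["curie"], f.get("label")), f.get("applies_to")
                )
                for f in doc["filters"]
            ],
            component_status=doc["component_status"],
            tokens_used=doc["tokens_used"],
            transcript=[tuple(t) for t in doc["transcript"]],
        )


@dataclass
class ClarificationRequest:
    """Issued when the accumulated state cannot yet build a valid query."""

    missing: list[str]
    prompt_text: str


_CLARIFICATION_PROMPTS = {
    "scope": (
        "Which collection should I query (a cohort or a dataset, and its id), "
        "and which entity type (e.g. individuals)?"
    ),
    "granularity": (
        "Should the answer be a yes/no (boolean), a count, or full records?"
    ),
}


# ---------------------------------------------------------------------------
# rule backend


_ENTITY_KEYWORDS = (
    ("individuals", "individuals"),
    ("people", "individuals"),
    ("patients", "individuals"),
    ("genomic variants", "g_variants"),
)

_GRANULARITY_PATTERNS = (
    ("how many", "count"),
    ("count", "count"),
    ("is there", "boolean"),
    ("are there", "boolean"),
    ("any", "boolean"),
    ("list", "record"),
    ("show", "record"),
    ("records", "record"),
)

_COLLECTION_RE = re.compile(
    r"\b(cohort|dataset)\s+([A-Za-z0-9._-]+)", re.IGNORECASE
)
_RS_TOKEN_RE = re.compile(r"\brs\d+\b", re.IGNORECASE)


class RuleBackend(ExtractorBackend):
    """Deterministic keyword-grammar extractor over packaged lexicons.

    Longest-match, left-to-right: the earliest keyword occurrence wins,
    ties broken by pattern length.  A pure function of its inputs:
    identical (task, utterance) pairs give identical candidates and
    costs.
    """

    deterministic = True

    def __init__(self, lexicon: Lexicon | None = None, rsid_table: RsidTable | None = None):
        self.lexicon = lexicon or Lexicon.packaged()
        self.rsid_table = rsid_table or RsidTable.packaged()

    def render_input(self, task: str, utterance: str) -> str:
        """The prompt the backend 'sees'; the basis of token accounting."""
        return f"[{task}] {utterance}"

    def extract(self, task: str, utterance: str, context: dict) -> ExtractResult:
        if task not in COMPONENTS:
            raise ExtractionError(f"unknown task {task!r}")
        cost = len(self.render_input(task, utterance).split())
        candidate = getattr(self, f"_extract_{task}")(utterance)
        return ExtractResult(candidate=candidate, token_cost=cost)

    def _extract_scope(self, utterance: str) -> ScopeCandidate | None:
        low = utterance.lower()
        cand = ScopeCandidate(has_genomic=bool(GENOMIC_TOKEN_RE.search(utterance)))
        m = _COLLECTION_RE.search(utterance)
        if m:
            cand.collection_scope = m.group(1).lower()
            cand.collection_id = m.group(2)
        hits = [
            (low.find(kw), -len(kw), entity)
            for kw, entity in _ENTITY_KEYWORDS
            if kw in low
        ]
        if hits:
            cand.entity_type = min(hits)[2]
        return None if cand.is_empty() else cand

    def _extract_granularity(self, utterance: str) -> str | None:
        low = utterance.lower()
        hits = []
        for pattern, gran in _GRANULARITY_PATTERNS:
            m = re.search(rf"\b{re.escape(pattern)}\b", low)
            if m:
                hits.append((m.start(), -len(pattern), gran))
        return min(hits)[2] if hits else None

    def _extract_variants(self, utterance: str) -> list[VariantDescriptor]:
        out = []
        for tok in _RS_TOKEN_RE.findall(utterance):
            try:
                out.append(resolve_rsid(tok.lower(), self.rsid_table))
            except UnknownRsidError:
                continue
        return out

    def _extract_filters(self, utterance: str) -> list[FilterClause]:
        # Ambiguous phrases are left out: they need user confirmation,
        # which the clarification loop owns, never the extractor.
        return [
            FilterClause(term=r.term)
            for r in scan_terms(utterance, self.lexicon)
            if r.status == "resolved"
        ]


# ---------------------------------------------------------------------------
# merging and orchestration


def merge_into_state(state: ExtractionState, component: str, candidate) -> ExtractionState:
    """Fold one extracted candidate into the session state (pure).

    Scalars (scope fields, granularity): newest non-empty value replaces
    the old.  Lists (variants, filters): set-union under canonical keys,
    keeping first-seen order — merging the same item twice is a no-op.
    """
    out = state.copy()
    if component == "scope":
        for attr in ("collection_scope", "collection_id", "entity_type"):
            value = getattr(candidate, attr)
            if value is not None:
                setattr(out, attr, value)
    elif component == "granularity":
        out.granularity = candidate
    elif component == "variants":
        seen = {v.key() for v in out.variants}
        for v in candidate:
            if v.key() not in seen:
                out.variants.append(v)
                seen.add(v.key())
    elif component == "filters":
        seen = {f.key() for f in out.filters}
        for f in candidate:
            if f.key() not in seen:
                out.filters.append(f)
                seen.add(f.key())
    else:
        raise ExtractionError(f"unknown component {component!r}")
    out.component_status[component] = "extracted"
    return out


def _is_empty_candidate(candidate) -> bool:
    if candidate is None:
        return True
    if isinstance(candidate, list):
        return len(candidate) == 0
    return False


def extract_parallel(
    utterance: str, backend: ExtractorBackend, state: ExtractionState
) -> ExtractionState:
    """Run all four extractors independently and merge their results.

    A failure of one extractor never prevents the other three from
    contributing; every invocation's token cost is paid.
    """
    if not utterance:
        raise ExtractionError("utterance must be non-empty")
    context = state.snapshot()
    out = state.copy()
    out.transcript.append(("user", utterance))
    for task in COMPONENTS:
        try:
            result = backend.extract(task, utterance, context)
        except Exception:
            out.component_status[task] = "failed"
            continue
        out.tokens_used += result.token_cost
        if not _is_empty_candidate(result.candidate):
            merged = merge_into_state(out, task, result.candidate)
            merged.transcript = out.transcript  # merge appends nothing here
            out = merged
    return out


def extract_multistep(
    utterance: str, backend: ExtractorBackend, state: ExtractionState
) -> ExtractionState:
    """Run the dependent chain scope → granularity → variants → filters.

    Each step receives prior step outputs in its context; the first
    failure aborts the chain, and the variants step is skipped when the
    scope step saw no genomic token in the utterance.
    """
    if not utterance:
        raise ExtractionError("utterance must be non-empty")
    context = dict(state.snapshot())
    out = state.copy()
    out.transcript.append(("user", utterance))
    chain_outputs: dict[str, object] = {}
    has_genomic = bool(GENOMIC_TOKEN_RE.search(utterance))
    for task in COMPONENTS:
        if task == "variants" and not has_genomic:
            continue  # purely phenotypic utterance: step is moot
        try:
            result = backend.extract(
                task, utterance, {**context, "chain_outputs": dict(chain_outputs)}
            )
        except Exception:
            out.component_status[task] = "failed"
            return out  # early abort: later components stay unset
        out.tokens_used += result.token_cost
        chain_outputs[task] = result.candidate
        if task == "scope" and isinstance(result.candidate, ScopeCandidate):
            has_genomic = has_genomic or result.candidate.has_genomic
        if not _is_empty_candidate(result.candidate):
            merged = merge_into_state(out, task, result.candidate)
            merged.transcript = out.transcript
            out = merged
    return out


ARCHITECTURES = {"parallel": extract_parallel, "multistep": extract_multistep}


def build_query(
    state: ExtractionState, default_collection: str = "DEFAULT"
) -> BeaconQuery | ClarificationRequest:
    """Turn accumulated state into a valid query, or ask for what's missing.

    Requires an entity type (scope) and a granularity; the collection
    scope/id default to (cohort, ``default_collection``) when unset —
    callers surface the built query for user confirmation either way.
    Missing components are reported in chain order, and the prompt
    addresses the first one only (one question per turn).
    """
    missing = []
    if state.entity_type is None:
        missing.append("scope")
    if state.granularity is None:
        missing.append("granularity")
    if missing:
        return ClarificationRequest(
            missing=missing, prompt_text=_CLARIFICATION_PROMPTS[missing[0]]
        )
    entity = state.entity_type
    return BeaconQuery(
        collection_scope=state.collection_scope or "cohort",
        collection_id=state.collection_id or default_collection,
        entity_type=entity,
        granularity=state.granularity,
        variants=list(state.variants),
        filters=[
            FilterClause(f.term, f.applies_to or entity) for f in state.filters
        ],
    )


# ---------------------------------------------------------------------------
# sessions (the multi-tab contract: independent, isolated states)


class SessionManager:
    """Independent extraction sessions keyed by tab id.

    Sessions share no mutable state: operations on one never alter
    another, so interleaved turns across tabs equal non-interleaved runs.
    """

    def __init__(self):
        self._sessions: dict[str, ExtractionState] = {}

    def new_session(self, tab_id: str | None = None) -> str:
        tab_id = tab_id or uuid.uuid4().hex[:8]
        if tab_id in self._sessions:
            raise ExtractionError(f"session {tab_id!r} already exists")
        self._sessions[tab_id] = ExtractionState()
        return tab_id

    def get(self, tab_id: str) -> ExtractionState:
        try:
            return self._sessions[tab_id]
        except KeyError:
            raise UnknownSessionError(tab_id) from None

    def update(self, tab_id: str, state: ExtractionState) -> None:
        if tab_id not in self._sessions:
            raise UnknownSessionError(tab_id)
        self._sessions[tab_id] = state

    def close(self, tab_id: str) -> None:
        if tab_id not in self._sessions:
            raise UnknownSessionError(tab_id)
        del self._sessions[tab_id]

    def list_sessions(self) -> list[str]:
        return sorted(self._sessions)


def export_transcript_jsonl(state: ExtractionState) -> str:
    """Session transcript as JSON Lines, one turn per line."""
    lines = [
        json.dumps({"role": role, "text": text}, sort_keys=True)
        for role, text in state.transcript
    ]
    return "\n".join(lines) + ("\n" if lines else "")
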