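"""Beacon-style query/response data model, validation and canonical JSON.

The model is a minimal dialect of the GA4GH Beacon v2 request/response
shape: a query targets one collection (a cohort or a dataset), one entity
type, and one response granularity, optionally constrained by ontology
filters (AND-combined) and variant descriptors.  Coordinates are 0-based
inclusive start throughout (Beacon convention); VCF input is converted at
load time.

Serialization is canonical: equal queries produce byte-identical JSON
(sorted keys, filters sorted by CURIE, empty lists emitted as empty
arrays), and byte-identical JSON parses back to equal queries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

COLLECTION_SCOPES = ("cohort", "dataset")
ENTITY_TYPES = ("individuals", "biosamples", "runs", "analyses", "g_variants")
GRANULARITIES = ("boolean", "count", "record")
#: boolean < count < record — also the ordering used for access control.
GRANULARITY_ORDER = {g: i for i, g in enumerate(GRANULARITIES)}

CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y", "MT")

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:[A-Za-z0-9._-]+$")
RSID_RE = re.compile(r"^rs[0-9]+$")
BASES_RE = re.compile(r"^[ACGTN]+$")


class BeaconModelError(Exception):
    """Base class for model-layer errors."""


class ParseError(BeaconModelError):
    """Raised when JSON cannot be parsed into a query; names the bad key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


class InvalidQueryError(BeaconModelError):
    """Raised when an operation requires a valid query; carries the report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(
            "query is not valid: missing=%s violations=%s"
            % (report.missing_fields, report.violations)
        )


def min_granularity(a: str, b: str) -> str:
    """The lower of two granularities under boolean < count < record."""
    return a if GRANULARITY_ORDER[a] <= GRANULARITY_ORDER[b] else b


def normalize_chromosome(label: str) -> str:
    """Strip a 'chr' prefix, warning when one was present."""
    if label.lower().startswith("chr"):
        stripped = label[3:]
        logger.warning("normalizing chromosome label %r to %r", label, stripped)
        return stripped
    return label


@dataclass(frozen=True)
class OntologyTerm:
    """An ontology concept, e.g. a SNOMED disease code."""

    curie: str
    label: str | None = None


@dataclass(frozen=True)
class FilterClause:
    """An ontology-coded predicate constraining an entity set.

    ``applies_to`` names the entity type the filter constrains; ``None``
    means "default to the query's entity type" and is resolved when a
    query is built.
    """

    term: OntologyTerm
    applies_to: str | None = None

    def key(self, default_entity: str | None = None) -> tuple[str, str | None]:
        return (self.term.curie, self.applies_to or default_entity)


@dataclass(frozen=True)
class VariantDescriptor:
    """A variant site, addressed by coordinates and/or dbSNP rsID.

    ``start`` is 0-based inclusive.  At least one of (reference_name,
    start) or rsid must be populated for the descriptor to be valid.
    """

    assembly_id: str = "GRCh38"
    reference_name: str | None = None
    start: int | None = None
    reference_bases: str | None = None
    alternate_bases: str | None = None
    rsid: str | None = None

    def key(self):
        """Canonical identity used for set-union merging and scoring."""
        if self.rsid is not None:
            return ("rsid", self.rsid)
        return (
            "coords",
            self.reference_name,
            self.start,
            self.reference_bases,
            self.alternate_bases,
        )


def _filter_sort_key(f: FilterClause):
    return (f.term.curie, f.applies_to or "")


def _variant_sort_key(v: VariantDescriptor):
    return (
        v.reference_name or "",
        -1 if v.start is None else v.start,
        v.rsid or "",
        v.reference_bases or "",
        v.alternate_bases or "",
    )


@dataclass
class BeaconQuery:
    """A structured Beacon query.  Filters combine with AND only.

    Filter and variant lists are kept in canonical sorted order so that
    equal queries serialize to byte-identical JSON and the round trip
    ``parse_query(serialize_query(q)) == q`` is an identity.  Duplicates
    are retained (validation reports them).
    """

    collection_scope: str | None = None
    collection_id: str | None = None
    entity_type: str | None = None
    granularity: str | None = None
    variants: list[VariantDescriptor] = field(default_factory=list)
    filters: list[FilterClause] = field(default_factory=list)
    combinator: str = "AND"

    def __post_init__(self):
        self.variants = sorted(self.variants, key=_variant_sort_key)
        self.filters = sorted(self.filters, key=_filter_sort_key)


@dataclass
class ValidationReport:
    valid: bool
    missing_fields: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)


@dataclass
class BeaconResponse:
    """A Beacon answer at the granularity the caller was allowed.

    Invariants (enforced by the engine, property-tested): ``exists ==
    (count > 0)`` whenever count is present, and ``count ==
    len(records)`` whenever records are present.
    """

    granularity_returned: str
    exists: bool
    count: int | None = None
    records: list[dict] | None = None
    downgraded: bool = False

    def to_dict(self) -> dict:
        out: dict = {
            "granularityReturned": self.granularity_returned,
            "exists": self.exists,
            "downgraded": self.downgraded,
        }
        if self.count is not None:
            out["count"] = self.count
        if self.records is not None:
            out["records"] = self.records
        return out


# ---------------------------------------------------------------------------
# validation


def _validate_variant(v: VariantDescriptor, idx: int, violations: list[str]) -> None:
    where = f"variants[{idx}]"
    has_coords = v.reference_name is not None and v.start is not None
    if not has_coords and v.rsid is None:
        violations.append(
            f"{where}: needs (reference_name, start) or rsid populated"
        )
    if v.start is not None and v.start < 0:
        violations.append(f"{where}: start must be >= 0, got {v.start}")
    if v.reference_name is not None and v.reference_name not in CHROMOSOMES:
        violations.append(
            f"{where}: unknown chromosome label {v.reference_name!r}"
        )
    if v.rsid is not None and not RSID_RE.match(v.rsid):
        violations.append(f"{where}: malformed rsid {v.rsid!r}")
    for attr in ("reference_bases", "alternate_bases"):
        val = getattr(v, attr)
        if val is not None and not BASES_RE.match(val):
            violations.append(f"{where}: {attr} {val!r} not over {{A,C,G,T,N}}")


def validate_query(q: BeaconQuery | dict) -> ValidationReport:
    """Check a possibly-partial query; never raises.

    Reports every absent required field (entity_type, granularity,
    collection_scope) and every constraint violation.  ``valid`` is true
    iff the query is executable as-is.
    """
    if isinstance(q, dict):
        q = BeaconQuery(**q)
    missing: list[str] = []
    violations: list[str] = []

    for name, allowed in (
        ("entity_type", ENTITY_TYPES),
        ("granularity", GRANULARITIES),
        ("collection_scope", COLLECTION_SCOPES),
    ):
        value = getattr(q, name)
        if value is None:
            missing.append(name)
        elif value not in allowed:
            violations.append(f"{name}: {value!r} not one of {allowed}")

    seen: set[tuple[str, str | None]] = set()
    for i, f in enumerate(q.filters):
        if not CURIE_RE.match(f.term.curie):
            violations.append(f"filters[{i}]: bad curie syntax {f.term.curie!r}")
        if f.applies_to is not None and f.applies_to not in ENTITY_TYPES:
            violations.append(
                f"filters[{i}]: applies_to {f.applies_to!r} not an entity type"
            )
        k = f.key(q.entity_type)
        if k in seen:
            violations.append(f"filters[{i}]: duplicate filter {k}")
        seen.add(k)

    for i, v in enumerate(q.variants):
        _validate_variant(v, i, violations)

    return ValidationReport(
        valid=not missing and not violations,
        missing_fields=missing,
        violations=violations,
    )


# ---------------------------------------------------------------------------
# canonical JSON serialization

_VARIANT_JSON_KEYS = {
    "assemblyId": "assembly_id",
    "referenceName": "reference_name",
    "start": "start",
    "referenceBases": "reference_bases",
    "alternateBases": "alternate_bases",
    "rsid": "rsid",
}


def serialize_query(q: BeaconQuery) -> str:
    """Emit the canonical JSON request document for a valid query.

    Sorted keys, UTF-8-safe, no trailing whitespace; empty filter and
    variant lists appear as empty arrays, never omitted keys.
    """
    report = validate_query(q)
    if not report.valid:
        raise InvalidQueryError(report)
    doc = {
        "collectionScope": q.collection_scope,
        "collectionId": q.collection_id,
        "entityType": q.entity_type,
        "requestedGranularity": q.granularity,
        "filters": [
            {"id": f.term.curie, "scope": f.applies_to, "label": f.term.label}
            for f in q.filters
        ],
        "requestParameters": {
            "variants": [
                {jk: getattr(v, attr) for jk, attr in _VARIANT_JSON_KEYS.items()}
                for v in q.variants
            ]
        },
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


_KNOWN_TOP_KEYS = {
    "collectionScope",
    "collectionId",
    "entityType",
    "requestedGranularity",
    "filters",
    "requestParameters",
}


def _require_enum(value, key: str, allowed) -> str:
    if value not in allowed:
        raise ParseError(key, f"{value!r} not one of {allowed}")
    return value


def parse_query(text: str) -> BeaconQuery:
    """Parse a JSON request document; unknown keys are ignored with a warning."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError("<document>", f"malformed JSON: {e}") from e
    if not isinstance(doc, dict):
        raise ParseError("<document>", "top level must be a JSON object")

    for key in sorted(set(doc) - _KNOWN_TOP_KEYS):
        logger.warning("ignoring unknown key %r in query document", key)

    scope = doc.get("collectionScope")
    if scope is not None:
        _require_enum(scope, "collectionScope", COLLECTION_SCOPES)
    entity = doc.get("entityType")
    if entity is not None:
        _require_enum(entity, "entityType", ENTITY_TYPES)
    gran = doc.get("requestedGranularity")
    if gran is not None:
        _require_enum(gran, "requestedGranularity", GRANULARITIES)

    filters = []
    for i, f in enumerate(doc.get("filters") or []):
        if not isinstance(f, dict) or "id" not in f:
            raise ParseError(f"filters[{i}]", "filter must be an object with 'id'")
        filters.append(
            FilterClause(
                term=OntologyTerm(curie=f["id"], label=f.get("label")),
                applies_to=f.get("scope"),
            )
        )

    variants = []
    params = doc.get("requestParameters") or {}
    for i, v in enumerate(params.get("variants") or []):
        if not isinstance(v, dict):
            raise ParseError(f"requestParameters.variants[{i}]", "must be an object")
        kwargs = {attr: v.get(jk) for jk, attr in _VARIANT_JSON_KEYS.items()}
        if kwargs["assembly_id"] is None:
            kwargs["assembly_id"] = "GRCh38"
        if kwargs["reference_name"] is not None:
            kwargs["reference_name"] = normalize_chromosome(kwargs["reference_name"])
        variants.append(VariantDescriptor(**kwargs))

    return BeaconQuery(
        collection_scope=scope,
        collection_id=doc.get("collectionId"),
        entity_type=entity,
        granularity=gran,
        variants=variants,
        filters=filters,
    )


def copy_query(q: BeaconQuery, **changes) -> BeaconQuery:
    """Shallow copy with field replacement (re-canonicalizes lists)."""
    return replace(q, **changes)
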