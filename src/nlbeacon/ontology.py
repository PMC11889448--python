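"""Free-text phrase → ontology term and rsID → coordinate resolution.

Lookups run against packaged, versioned JSON lexicons rather than a live
terminology service, so resolution is deterministic and hermetic.  The
packaged fixture lexicon carries synthetic positions/alleles (its version
string says so); only the chromosome assignments of the two worked-example
markers (rs28602900 on X, rs356181 on 4) are biologically meaningful.

Ambiguity is surfaced, never auto-resolved: a phrase with several
candidate terms comes back as ``ambiguous`` and the caller must confirm
with the user.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import RSID_RE, OntologyTerm, VariantDescriptor, normalize_chromosome

_APOSTROPHES = "'’ʼ"
_EDGE_PUNCT = ".,!?;:()[]\"" + _APOSTROPHES


class LexiconError(Exception):
    """Malformed lexicon/rsid-table file."""


class MalformedRsidError(ValueError):
    """The string does not look like an rsID at all."""


class UnknownRsidError(KeyError):
    """Well-formed rsID absent from the table."""


def normalize_phrase(phrase: str) -> str:
    """Lower-case, strip possessive apostrophes, collapse whitespace.

    "Parkinson's  Disease" → "parkinsons disease".  Token-edge punctuation
    is stripped so phrases lifted from running text normalize cleanly.
    """
    s = phrase.lower()
    for ch in _APOSTROPHES:
        s = s.replace(ch, "")
    tokens = [t.strip(_EDGE_PUNCT) for t in s.split()]
    return " ".join(t for t in tokens if t)


@dataclass
class Lexicon:
    """phrase → candidate ontology terms, from a versioned JSON file."""

    entries: dict[str, list[OntologyTerm]]
    version: str

    def __post_init__(self):
        for phrase, cands in self.entries.items():
            if phrase != normalize_phrase(phrase):
                raise LexiconError(f"phrase {phrase!r} is not normalized")
            if not cands:
                raise LexiconError(f"phrase {phrase!r} has no candidates")
            if len({c.curie for c in cands}) != len(cands):
                raise LexiconError(f"phrase {phrase!r} has duplicate candidates")

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls._from_doc(doc, path)

    @classmethod
    def _from_doc(cls, doc: dict, origin) -> "Lexicon":
        try:
            entries = {
                phrase: [OntologyTerm(c["curie"], c.get("label")) for c in cands]
                for phrase, cands in doc["terms"].items()
            }
            return cls(entries=entries, version=doc["version"])
        except (KeyError, TypeError) as e:
            raise LexiconError(f"malformed lexicon {origin}: {e}") from e

    @classmethod
    def packaged(cls) -> "Lexicon":
        text = resources.files("nlbeacon.data").joinpath("lexicon.json").read_text()
        return cls._from_doc(json.loads(text), "packaged lexicon.json")


@dataclass
class RsidTable:
    """rsID → (assembly, chromosome, 0-based start, ref, alt)."""

    entries: dict[str, VariantDescriptor]
    version: str

    def __post_init__(self):
        for rsid, v in self.entries.items():
            if not RSID_RE.match(rsid):
                raise LexiconError(f"bad rsid key {rsid!r}")
            if v.start is None or v.start < 0:
                raise LexiconError(f"rsid {rsid!r} has bad start {v.start!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RsidTable":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls._from_doc(doc, path)

    @classmethod
    def _from_doc(cls, doc: dict, origin) -> "RsidTable":
        try:
            entries = {
                rsid: VariantDescriptor(
                    assembly_id=rec["assembly"],
                    reference_name=normalize_chromosome(rec["chrom"]),
                    start=rec["start"],
                    reference_bases=rec["ref"],
                    alternate_bases=rec["alt"],
                    rsid=rsid,
                )
                for rsid, rec in doc["rsids"].items()
            }
            return cls(entries=entries, version=doc["version"])
        except (KeyError, TypeError) as e:
            raise LexiconError(f"malformed rsid table {origin}: {e}") from e

    @classmethod
    def packaged(cls) -> "RsidTable":
        text = resources.files("nlbeacon.data").joinpath("rsids.json").read_text()
        return cls._from_doc(json.loads(text), "packaged rsids.json")


@dataclass
class TermResolution:
    """Outcome of a phrase lookup: resolved / ambiguous / unknown."""

    status: str  # "resolved" | "ambiguous" | "unknown"
    phrase: str
    term: OntologyTerm | None = None
    candidates: list[OntologyTerm] = field(default_factory=list)


def resolve_term(phrase: str, lexicon: Lexicon) -> TermResolution:
    """Longest-normalized-match lookup of a phrase.

    The full normalized phrase is tried first; failing that, the longest
    contained token span present in the lexicon wins (ties broken by
    earliest position).  One candidate → resolved; several → ambiguous
    with candidates in lexicon order; none → unknown.
    """
    if not phrase:
        raise ValueError("phrase must be non-empty")
    norm = normalize_phrase(phrase)
    tokens = norm.split()
    for span_len in range(len(tokens), 0, -1):
        for start in range(0, len(tokens) - span_len + 1):
            span = " ".join(tokens[start : start + span_len])
            cands = lexicon.entries.get(span)
            if cands is None:
                continue
            if len(cands) == 1:
                return TermResolution("resolved", span, term=cands[0])
            return TermResolution("ambiguous", span, candidates=list(cands))
    return TermResolution("unknown", norm)


def scan_terms(utterance: str, lexicon: Lexicon) -> list[TermResolution]:
    """Greedy longest-match, left-to-right scan of an utterance.

    Returns one resolution per matched span, in utterance order; matched
    tokens are consumed so spans never overlap.
    """
    tokens = normalize_phrase(utterance).split()
    max_len = max((len(p.split()) for p in lexicon.entries), default=0)
    out: list[TermResolution] = []
    i = 0
    while i < len(tokens):
        matched = False
        for span_len in range(min(max_len, len(tokens) - i), 0, -1):
            span = " ".join(tokens[i : i + span_len])
            cands = lexicon.entries.get(span)
            if cands is not None:
                if len(cands) == 1:
                    out.append(TermResolution("resolved", span, term=cands[0]))
                else:
                    out.append(
                        TermResolution("ambiguous", span, candidates=list(cands))
                    )
                i += span_len
                matched = True
                break
        if not matched:
            i += 1
    return out


def resolve_rsid(rsid: str, table: RsidTable) -> VariantDescriptor:
    """Look an rsID up, returning a fully-populated descriptor.

    Distinguishes "malformed" (not ``rs`` + digits) from "well-formed but
    absent from the table".
    """
    if not RSID_RE.match(rsid):
        raise MalformedRsidError(f"{rsid!r} does not match rs[0-9]+")
    try:
        return table.entries[rsid]
    except KeyError:
        raise UnknownRsidError(rsid) from None
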