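"""Local cohort store and deterministic Beacon query execution.

This module is the local stand-in for a production Beacon node: it loads a
cohort from a VCF (genotypes) plus a phenotype CSV (karyotypic sex,
ontology-coded conditions), and answers validated queries at boolean,
count or record granularity under per-user access control.

Semantics:

* Filters are ontology-condition predicates, AND-combined.
* "Mutations in" a variant means carrier status: alternate-allele dosage
  >= 1 at that site.  Zygosity-specific predicates are out of scope.
* Access control downgrades — a response never exceeds the user's maximum
  granularity, and carries ``downgraded=True`` when it was reduced.
* Responses are deterministic: record payloads are sorted by
  individual_id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .model import (
    GRANULARITY_ORDER,
    BeaconQuery,
    BeaconResponse,
    InvalidQueryError,
    ValidationReport,
    VariantDescriptor,
    min_granularity,
    normalize_chromosome,
    validate_query,
)

logger = logging.getLogger(__name__)

KARYOTYPIC_SEXES = ("XX", "XY", "X0", "XXY", "other", "unknown")

_RSID_TOKEN = re.compile(r"^rs[0-9]+$")

#: (reference_name, start, ref, alt) — the canonical site identity.
VariantKey = tuple[str, int, str, str]


class CohortLoadError(Exception):
    """Unreadable/malformed input file; message names file and line."""


class CohortNotFoundError(KeyError):
    """Query collection_id does not match the cohort."""


class UnsupportedEntityError(Exception):
    """Entity type is schema-valid but not executable by this engine."""


class AccessError(PermissionError):
    """The user's granularity does not permit the requested computation."""


@dataclass
class Individual:
    individual_id: str
    karyotypic_sex: str
    conditions: frozenset[str]
    genotypes: dict[VariantKey, int] = field(default_factory=dict)


@dataclass
class Cohort:
    cohort_id: str
    individuals: list[Individual]
    sites: list[VariantDescriptor]

    def site_keys(self) -> set[VariantKey]:
        return {_site_key(s) for s in self.sites}


@dataclass
class UserAccess:
    user_id: str
    max_granularity: str = "record"


FULL_ACCESS = UserAccess(user_id="local-admin", max_granularity="record")


def _site_key(site: VariantDescriptor) -> VariantKey:
    return (
        site.reference_name,
        site.start,
        site.reference_bases,
        site.alternate_bases,
    )


# ---------------------------------------------------------------------------
# loading


def _load_phenotypes(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as e:
        raise CohortLoadError(f"{path}: cannot read phenotype CSV: {e}") from e
    required = {"individual_id", "karyotypic_sex", "conditions"}
    missing = required - set(df.columns)
    if missing:
        raise CohortLoadError(f"{path}: missing columns {sorted(missing)}")
    dup = df["individual_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        raise CohortLoadError(
            f"{path}: line {line}: duplicate individual_id "
            f"{df['individual_id'][dup.idxmax()]!r}"
        )
    bad_sex = ~df["karyotypic_sex"].isin(KARYOTYPIC_SEXES)
    if bad_sex.any():
        line = int(bad_sex.idxmax()) + 2
        raise CohortLoadError(
            f"{path}: line {line}: unknown karyotypic_sex "
            f"{df['karyotypic_sex'][bad_sex.idxmax()]!r}"
        )
    return df


def load_cohort(vcf: str | Path, phenotypes: str | Path, cohort_id: str) -> Cohort:
    """Load a cohort from a GT-only VCF and a phenotype CSV.

    Sample IDs are reconciled by exact match; individuals present in only
    one source are dropped with a warning.  VCF 1-based POS becomes
    0-based start; multi-allelic records are split into bi-allelic sites.
    """
    pheno = _load_phenotypes(phenotypes)

    try:
        reader = VCF(str(vcf), gts012=False)
    except OSError as e:
        raise CohortLoadError(f"{vcf}: cannot read VCF: {e}") from e

    vcf_samples = list(reader.samples)
    if len(set(vcf_samples)) != len(vcf_samples):
        raise CohortLoadError(f"{vcf}: duplicate sample IDs in header")

    sites: list[VariantDescriptor] = []
    dosages: list[list[int]] = []  # per site, per VCF sample
    for rec in reader:
        chrom = normalize_chromosome(rec.CHROM)
        rsid = rec.ID if rec.ID and _RSID_TOKEN.match(rec.ID) else None
        gts = rec.genotypes  # [[a0, a1, phased], ...]; haploid [[a0, phased]]
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            sites.append(
                VariantDescriptor(
                    assembly_id="GRCh38",
                    reference_name=chrom,
                    start=rec.start,  # cyvcf2 start is already 0-based
                    reference_bases=rec.REF,
                    alternate_bases=alt,
                    rsid=rsid,
                )
            )
            dosages.append(
                [sum(1 for a in g[:-1] if a == alt_idx) for g in gts]
            )
    reader.close()

    pheno_ids = list(pheno["individual_id"])
    shared = set(vcf_samples) & set(pheno_ids)
    for missing_id in sorted(set(vcf_samples) ^ set(pheno_ids)):
        source = "phenotype table" if missing_id in pheno_ids else "VCF"
        logger.warning(
            "dropping individual %r: present only in %s", missing_id, source
        )

    keys = [_site_key(s) for s in sites]
    col = {sid: i for i, sid in enumerate(vcf_samples)}
    individuals = []
    for row in pheno.itertuples(index=False):
        if row.individual_id not in shared:
            continue
        j = col[row.individual_id]
        conditions = frozenset(
            c.strip() for c in row.conditions.split(";") if c.strip()
        )
        individuals.append(
            Individual(
                individual_id=row.individual_id,
                karyotypic_sex=row.karyotypic_sex,
                conditions=conditions,
                genotypes={k: dosages[i][j] for i, k in enumerate(keys)},
            )
        )
    return Cohort(cohort_id=cohort_id, individuals=individuals, sites=sites)


# ---------------------------------------------------------------------------
# query execution


def _sites_matching(descriptor: VariantDescriptor, cohort: Cohort) -> list[VariantKey]:
    """Cohort sites addressed by one query descriptor."""
    out = []
    for site in cohort.sites:
        if descriptor.reference_name is not None and descriptor.start is not None:
            if (
                site.reference_name != descriptor.reference_name
                or site.start != descriptor.start
            ):
                continue
            if (
                descriptor.reference_bases is not None
                and site.reference_bases != descriptor.reference_bases
            ):
                continue
            if (
                descriptor.alternate_bases is not None
                and site.alternate_bases != descriptor.alternate_bases
            ):
                continue
        elif descriptor.rsid is not None:
            if site.rsid != descriptor.rsid:
                continue
        else:
            continue
        out.append(_site_key(site))
    return out


def individual_matches(ind: Individual, q: BeaconQuery, cohort: Cohort) -> bool:
    """Does one individual satisfy every filter and carry every variant?"""
    for f in q.filters:
        if f.term.curie not in ind.conditions:
            return False
    for descriptor in q.variants:
        keys = _sites_matching(descriptor, cohort)
        if not any(ind.genotypes.get(k, 0) >= 1 for k in keys):
            return False
    return True


def _matching_individuals(q: BeaconQuery, cohort: Cohort) -> list[Individual]:
    hits = [i for i in cohort.individuals if individual_matches(i, q, cohort)]
    return sorted(hits, key=lambda i: i.individual_id)


def _record_payload(ind: Individual) -> dict:
    return {
        "individual_id": ind.individual_id,
        "karyotypic_sex": ind.karyotypic_sex,
        "conditions": sorted(ind.conditions),
    }


def _site_payload(site: VariantDescriptor) -> dict:
    return {
        "assembly_id": site.assembly_id,
        "reference_name": site.reference_name,
        "start": site.start,
        "reference_bases": site.reference_bases,
        "alternate_bases": site.alternate_bases,
        "rsid": site.rsid,
    }


def _respond(
    granularity: str, n: int, records: list[dict] | None, downgraded: bool
) -> BeaconResponse:
    if granularity == "boolean":
        return BeaconResponse("boolean", exists=n > 0, downgraded=downgraded)
    if granularity == "count":
        return BeaconResponse("count", exists=n > 0, count=n, downgraded=downgraded)
    return BeaconResponse(
        "record", exists=n > 0, count=n, records=records, downgraded=downgraded
    )


def execute(q: BeaconQuery, cohort: Cohort, user: UserAccess) -> BeaconResponse:
    """Execute a valid query, answering at min(requested, allowed) granularity."""
    report = validate_query(q)
    if not report.valid:
        raise InvalidQueryError(report)
    if q.collection_id != cohort.cohort_id:
        raise CohortNotFoundError(q.collection_id)
    if q.entity_type not in ("individuals", "g_variants"):
        raise UnsupportedEntityError(
            f"entity type {q.entity_type!r} is validated but not executable "
            "by this engine (supported: individuals, g_variants)"
        )

    effective = min_granularity(q.granularity, user.max_granularity)
    downgraded = effective != q.granularity

    if q.entity_type == "individuals":
        hits = _matching_individuals(q, cohort)
        records = [_record_payload(i) for i in hits] if effective == "record" else None
        return _respond(effective, len(hits), records, downgraded)

    # g_variants: sites addressed by the descriptors (all sites when the
    # descriptor list is empty) that are carried by >= 1 filter-satisfying
    # individual.
    filter_query = BeaconQuery(
        collection_scope=q.collection_scope,
        collection_id=q.collection_id,
        entity_type="individuals",
        granularity=q.granularity,
        filters=list(q.filters),
    )
    eligible = [i for i in cohort.individuals if individual_matches(i, filter_query, cohort)]
    if q.variants:
        addressed: set[VariantKey] = set()
        for d in q.variants:
            addressed.update(_sites_matching(d, cohort))
    else:
        addressed = cohort.site_keys()
    matching_sites = [
        s
        for s in cohort.sites
        if _site_key(s) in addressed
        and any(i.genotypes.get(_site_key(s), 0) >= 1 for i in eligible)
    ]
    matching_sites.sort(key=_site_key)
    records = (
        [_site_payload(s) for s in matching_sites] if effective == "record" else None
    )
    return _respond(effective, len(matching_sites), records, downgraded)


def carrier_table(
    q: BeaconQuery,
    cohort: Cohort,
    stratify_by: str = "karyotypic_sex",
    user: UserAccess = FULL_ACCESS,
) -> dict[str, int]:
    """Counts of query-satisfying individuals per stratum.

    Strata are every value observed in the cohort, so strata matching
    nobody appear with count 0.  Requires count-level access or better.
    """
    if stratify_by != "karyotypic_sex":
        raise ValueError(f"unsupported stratification field {stratify_by!r}")
    if GRANULARITY_ORDER[user.max_granularity] < GRANULARITY_ORDER["count"]:
        raise AccessError(
            f"user {user.user_id!r} is limited to {user.max_granularity} "
            "granularity; carrier tables need count access"
        )
    report = validate_query(q)
    if not report.valid:
        raise InvalidQueryError(report)
    if q.collection_id != cohort.cohort_id:
        raise CohortNotFoundError(q.collection_id)
    table = {
        sex: 0
        for sex in sorted({i.karyotypic_sex for i in cohort.individuals})
    }
    for ind in cohort.individuals:
        if individual_matches(ind, q, cohort):
            table[ind.karyotypic_sex] += 1
    return table
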