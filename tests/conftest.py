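"""Shared fixtures: a hand-built toy cohort, backends, and an independent
naive query enumerator used as the oracle for the engine."""

from __future__ import annotations

import numpy as np
import pytest

from nlbeacon import engine, extraction, model
from nlbeacon.extraction import ExtractorBackend, ExtractResult
from nlbeacon.model import BeaconQuery, FilterClause, OntologyTerm, VariantDescriptor

TOY_VCF = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=4>\n"
    "##contig=<ID=X>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tIND_A\tIND_B\tIND_C\tIND_D\n"
    "4\t2000001\trs356181\tT\tC\t.\tPASS\t.\tGT\t0/1\t1/1\t0/1\t0/0\n"
    "X\t1000001\trs28602900\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/1\t0/0\n"
)

TOY_CSV = (
    "individual_id,karyotypic_sex,conditions\n"
    "IND_A,XY,TERM:PD\n"
    "IND_B,XY,TERM:PD\n"
    "IND_C,XX,TERM:PD\n"
    "IND_D,XX,\n"
)


@pytest.fixture()
def toy_cohort_files(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    csv = tmp_path / "toy.phenotypes.csv"
    csv.write_text(TOY_CSV)
    return vcf, csv


@pytest.fixture()
def toy_cohort(toy_cohort_files):
    vcf, csv = toy_cohort_files
    return engine.load_cohort(vcf, csv, "TOY")


@pytest.fixture()
def rule_backend():
    return extraction.RuleBackend()


class FailingBackend(ExtractorBackend):
    """Wraps another backend, raising on the configured tasks."""

    deterministic = True

    def __init__(self, inner: ExtractorBackend, fail_on: set[str]):
        self.inner = inner
        self.fail_on = set(fail_on)

    def extract(self, task, utterance, context) -> ExtractResult:
        if task in self.fail_on:
            raise RuntimeError(f"simulated backend failure on {task}")
        return self.inner.extract(task, utterance, context)


@pytest.fixture()
def failing_backend_factory(rule_backend):
    return lambda *tasks: FailingBackend(rule_backend, set(tasks))


# ---------------------------------------------------------------------------
# independent naive enumerator (the engine oracle)


def naive_execute(q: BeaconQuery, cohort: engine.Cohort) -> list[str]:
    """Brute-force re-check of every individual against every clause.

    Independent of the engine's matching code; returns the sorted ids of
    matching individuals.
    """
    hits = []
    for ind in cohort.individuals:
        ok = True
        for f in q.filters:
            if f.term.curie not in ind.conditions:
                ok = False
        for vd in q.variants:
            carried = False
            for site in cohort.sites:
                if vd.reference_name is not None and vd.start is not None:
                    same = (
                        site.reference_name == vd.reference_name
                        and site.start == vd.start
                        and (
                            vd.reference_bases is None
                            or site.reference_bases == vd.reference_bases
                        )
                        and (
                            vd.alternate_bases is None
                            or site.alternate_bases == vd.alternate_bases
                        )
                    )
                elif vd.rsid is not None:
                    same = site.rsid == vd.rsid
                else:
                    same = False
                if same:
                    key = (
                        site.reference_name,
                        site.start,
                        site.reference_bases,
                        site.alternate_bases,
                    )
                    if ind.genotypes.get(key, 0) >= 1:
                        carried = True
            if not carried:
                ok = False
        if ok:
            hits.append(ind.individual_id)
    return sorted(hits)


# ---------------------------------------------------------------------------
# random cohort / query generators for property suites

_CURIE_POOL = [f"TERM:C{i}" for i in range(6)]
_SITE_POOL = [
    VariantDescriptor(
        reference_name=chrom,
        start=start,
        reference_bases=ref,
        alternate_bases=alt,
        rsid=rsid,
    )
    for chrom, start, ref, alt, rsid in [
        ("1", 100, "A", "G", "rs11"),
        ("1", 100, "A", "T", None),  # multi-allelic sibling
        ("2", 200, "C", "T", "rs22"),
        ("4", 2000000, "T", "C", "rs356181"),
        ("X", 1000000, "C", "T", "rs28602900"),
        ("MT", 50, "G", "A", None),
    ]
]


def random_cohort(rng: np.random.Generator, max_n: int = 50) -> engine.Cohort:
    n = int(rng.integers(0, max_n + 1))
    n_sites = int(rng.integers(0, len(_SITE_POOL) + 1))
    site_idx = rng.choice(len(_SITE_POOL), size=n_sites, replace=False)
    sites = [_SITE_POOL[i] for i in sorted(site_idx)]
    individuals = []
    for i in range(n):
        sex = "XY" if rng.random() < 0.5 else "XX"
        conditions = frozenset(
            c for c in _CURIE_POOL if rng.random() < 0.35
        )
        genotypes = {}
        for site in sites:
            max_dose = 1 if (site.reference_name == "X" and sex == "XY") else 2
            genotypes[
                (
                    site.reference_name,
                    site.start,
                    site.reference_bases,
                    site.alternate_bases,
                )
            ] = int(rng.integers(0, max_dose + 1))
        individuals.append(
            engine.Individual(
                individual_id=f"I{i:03d}",
                karyotypic_sex=sex,
                conditions=conditions,
                genotypes=genotypes,
            )
        )
    return engine.Cohort(cohort_id="RND", individuals=individuals, sites=sites)


def random_query(rng: np.random.Generator, cohort: engine.Cohort) -> BeaconQuery:
    filters = [
        FilterClause(OntologyTerm(c), "individuals")
        for c in _CURIE_POOL
        if rng.random() < 0.3
    ]
    variants = []
    for site in _SITE_POOL:  # may reference sites absent from the cohort
        if rng.random() < 0.25:
            if site.rsid is not None and rng.random() < 0.5:
                variants.append(VariantDescriptor(rsid=site.rsid))
            else:
                variants.append(site)
    return BeaconQuery(
        collection_scope="cohort",
        collection_id=cohort.cohort_id,
        entity_type="individuals",
        granularity=("boolean", "count", "record")[int(rng.integers(3))],
        variants=variants,
        filters=filters,
    )


def random_valid_query(rng: np.random.Generator) -> BeaconQuery:
    """A random structurally-valid query (for serialization round trips)."""
    curies = [c for c in _CURIE_POOL if rng.random() < 0.4]
    filters = [
        FilterClause(
            OntologyTerm(c, label=None if rng.random() < 0.5 else f"label {c}"),
            None
            if rng.random() < 0.3
            else model.ENTITY_TYPES[int(rng.integers(len(model.ENTITY_TYPES)))],
        )
        for c in curies
    ]
    variants = [s for s in _SITE_POOL if rng.random() < 0.3]
    return BeaconQuery(
        collection_scope=model.COLLECTION_SCOPES[int(rng.integers(2))],
        collection_id=f"C{int(rng.integers(100))}",
        entity_type=model.ENTITY_TYPES[int(rng.integers(len(model.ENTITY_TYPES)))],
        granularity=model.GRANULARITIES[int(rng.integers(3))],
        variants=variants,
        filters=filters,
    )
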