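"""Cohort loading and deterministic query execution with access control."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_execute, random_cohort, random_query

from nlbeacon import engine
from nlbeacon.engine import (
    AccessError,
    CohortLoadError,
    CohortNotFoundError,
    Individual,
    UnsupportedEntityError,
    UserAccess,
    carrier_table,
    execute,
    load_cohort,
)
from nlbeacon.model import (
    BeaconQuery,
    FilterClause,
    OntologyTerm,
    VariantDescriptor,
)

PD = FilterClause(OntologyTerm("TERM:PD"), "individuals")
CHR4_SITE = VariantDescriptor(
    reference_name="4", start=2000000, reference_bases="T", alternate_bases="C",
    rsid="rs356181",
)


def toy_query(**overrides):
    kwargs = dict(
        collection_scope="cohort",
        collection_id="TOY",
        entity_type="individuals",
        granularity="count",
    )
    kwargs.update(overrides)
    return BeaconQuery(**kwargs)


class TestLoadCohort:
    def test_counts_and_coordinate_conversion(self, toy_cohort):
        assert len(toy_cohort.individuals) == 4
        assert len(toy_cohort.sites) == 2
        # VCF POS 2000001 → 0-based start 2000000
        chr4 = [s for s in toy_cohort.sites if s.reference_name == "4"][0]
        assert chr4.start == 2000000
        assert chr4.rsid == "rs356181"

    def test_genotype_dosages(self, toy_cohort):
        by_id = {i.individual_id: i for i in toy_cohort.individuals}
        key = ("4", 2000000, "T", "C")
        assert by_id["IND_A"].genotypes[key] == 1
        assert by_id["IND_B"].genotypes[key] == 2
        assert by_id["IND_D"].genotypes[key] == 0

    def test_unmatched_individual_dropped_with_warning(
        self, toy_cohort_files, caplog
    ):
        vcf, csv = toy_cohort_files
        csv.write_text(csv.read_text() + "IND_E,XX,TERM:PD\n")
        with caplog.at_level("WARNING"):
            cohort = load_cohort(vcf, csv, "TOY")
        assert len(cohort.individuals) == 4
        assert any("IND_E" in r.message for r in caplog.records)

    def test_duplicate_individual_id_is_load_error(self, toy_cohort_files):
        vcf, csv = toy_cohort_files
        csv.write_text(csv.read_text() + "IND_A,XY,\n")
        with pytest.raises(CohortLoadError, match="line 6"):
            load_cohort(vcf, csv, "TOY")

    def test_missing_column_is_load_error(self, toy_cohort_files, tmp_path):
        vcf, _ = toy_cohort_files
        bad = tmp_path / "bad.csv"
        bad.write_text("individual_id,conditions\nIND_A,\n")
        with pytest.raises(CohortLoadError, match="karyotypic_sex"):
            load_cohort(vcf, bad, "TOY")

    def test_multiallelic_records_split(self, tmp_path):
        vcf = tmp_path / "ma.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t101\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
        )
        csv = tmp_path / "ma.csv"
        csv.write_text("individual_id,karyotypic_sex,conditions\nS1,XX,\n")
        cohort = load_cohort(vcf, csv, "MA")
        assert len(cohort.sites) == 2
        ind = cohort.individuals[0]
        assert ind.genotypes[("1", 100, "A", "G")] == 1
        assert ind.genotypes[("1", 100, "A", "T")] == 1


class TestExecute:
    def test_filter_count_matches_brute_force(self, toy_cohort):
        q = toy_query(filters=[PD])
        resp = execute(q, toy_cohort, engine.FULL_ACCESS)
        assert resp.count == 3  # IND_A, IND_B, IND_C carry TERM:PD
        assert resp.exists
        assert resp.count == len(naive_execute(q, toy_cohort))

    def test_empty_cohort_boolean_false(self):
        empty = engine.Cohort(cohort_id="E", individuals=[], sites=[])
        q = toy_query(collection_id="E", granularity="boolean")
        resp = execute(q, empty, engine.FULL_ACCESS)
        assert resp.exists is False
        assert resp.count is None

    def test_access_downgrade_flagged(self, toy_cohort):
        q = toy_query(granularity="record")
        user = UserAccess("guest", max_granularity="boolean")
        resp = execute(q, toy_cohort, user)
        assert resp.granularity_returned == "boolean"
        assert resp.downgraded is True
        assert resp.count is None and resp.records is None

    def test_record_payloads_sorted_and_minimal(self, toy_cohort):
        q = toy_query(granularity="record", filters=[PD])
        resp = execute(q, toy_cohort, engine.FULL_ACCESS)
        ids = [r["individual_id"] for r in resp.records]
        assert ids == sorted(ids)
        assert set(resp.records[0]) == {
            "individual_id", "karyotypic_sex", "conditions",
        }
        assert resp.count == len(resp.records)

    def test_variant_and_filter_conjunction(self, toy_cohort):
        q = toy_query(
            filters=[PD],
            variants=[VariantDescriptor(rsid="rs28602900")],
        )
        resp = execute(q, toy_cohort, engine.FULL_ACCESS)
        assert resp.count == 2  # IND_B and IND_C carry the X marker + PD

    def test_cohort_id_mismatch(self, toy_cohort):
        with pytest.raises(CohortNotFoundError):
            execute(toy_query(collection_id="OTHER"), toy_cohort, engine.FULL_ACCESS)

    def test_unsupported_entity_types(self, toy_cohort):
        q = toy_query(entity_type="biosamples")
        with pytest.raises(UnsupportedEntityError):
            execute(q, toy_cohort, engine.FULL_ACCESS)

    def test_g_variants_counts_matching_sites(self, toy_cohort):
        q = toy_query(entity_type="g_variants")
        resp = execute(q, toy_cohort, engine.FULL_ACCESS)
        assert resp.count == 2  # both toy sites have at least one carrier


class TestCarrierTable:
    def test_sex_stratified_counts(self, toy_cohort):
        q = toy_query(filters=[PD], variants=[CHR4_SITE])
        assert carrier_table(q, toy_cohort) == {"XY": 2, "XX": 1}

    def test_query_matching_nobody_keeps_zero_strata(self, toy_cohort):
        q = toy_query(filters=[FilterClause(OntologyTerm("TERM:NONE"), "individuals")])
        assert carrier_table(q, toy_cohort) == {"XY": 0, "XX": 0}

    def test_boolean_user_denied(self, toy_cohort):
        user = UserAccess("guest", max_granularity="boolean")
        with pytest.raises(AccessError):
            carrier_table(toy_query(), toy_cohort, user=user)


class TestEngineProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_engine_equals_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng)
        q = random_query(rng, cohort)
        resp = execute(q, cohort, engine.FULL_ACCESS)
        expected = naive_execute(q, cohort)
        assert resp.exists == (len(expected) > 0)
        if resp.count is not None:
            assert resp.count == len(expected)
        if resp.records is not None:
            assert [r["individual_id"] for r in resp.records] == expected

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_determinism_and_matching_increment(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng)
        q = random_query(rng, cohort)

        r1 = execute(q, cohort, engine.FULL_ACCESS)
        r2 = execute(q, copy.deepcopy(cohort), engine.FULL_ACCESS)
        assert r1 == r2

        # adding an individual that matches raises count by exactly 1
        match_conditions = frozenset(f.term.curie for f in q.filters)
        genotypes = {
            (s.reference_name, s.start, s.reference_bases, s.alternate_bases): 1
            for s in cohort.sites
        }
        bigger = copy.deepcopy(cohort)
        bigger.individuals.append(
            Individual("ZZZ_NEW", "XX", match_conditions, genotypes)
        )
        r3 = execute(
            BeaconQuery(
                collection_scope=q.collection_scope,
                collection_id=q.collection_id,
                entity_type=q.entity_type,
                granularity="count",
                variants=[
                    v for v in q.variants
                    if naive_matchable(v, cohort)
                ],
                filters=list(q.filters),
            ),
            bigger,
            engine.FULL_ACCESS,
        )
        base = execute(
            BeaconQuery(
                collection_scope=q.collection_scope,
                collection_id=q.collection_id,
                entity_type=q.entity_type,
                granularity="count",
                variants=[
                    v for v in q.variants
                    if naive_matchable(v, cohort)
                ],
                filters=list(q.filters),
            ),
            cohort,
            engine.FULL_ACCESS,
        )
        assert r3.count == base.count + 1
        assert r3.exists


def naive_matchable(vd, cohort):
    """Variant descriptors addressing at least one site of the cohort."""
    for site in cohort.sites:
        if vd.reference_name is not None and vd.start is not None:
            if (
                site.reference_name == vd.reference_name
                and site.start == vd.start
                and (vd.reference_bases in (None, site.reference_bases))
                and (vd.alternate_bases in (None, site.alternate_bases))
            ):
                return True
        elif vd.rsid is not None and site.rsid == vd.rsid:
            return True
    return False
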