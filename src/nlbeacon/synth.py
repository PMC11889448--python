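"""Synthetic cohorts with controlled genotype–sex–disease structure, and
synthetic gold extraction sets.

The cohort generator draws individuals independently: karyotypic sex ~
Bernoulli(sex_ratio for XY), disease ~ Bernoulli(prevalence), and carrier
status per marker ~ Bernoulli of a frequency that depends on the
(sex, disease) cell.  The designed sex effect is disease-specific: only
diseased XY individuals get the scaled frequency ``ratio ×
carrier_freq_female_diseased``; every other cell uses the female-diseased
frequency unchanged.  Carrier status is generated directly rather than
via allele frequencies and Hardy–Weinberg because every downstream
computation is carrier-based; autosomal carriers get dosage 1 or 2 with
equal probability, X-linked XY carriers always dosage 1 (hemizygous).

The packaged preset emulates the headline structure of the worked
Parkinson's example: an autosomal chromosome-4 marker enriched 1.4× in
diseased XY individuals versus an X-linked marker with no sex difference.
Prevalence, sex ratio and cohort size are generator conveniences, not
estimates of any real cohort.

Everything is deterministic given the design seed: equal seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import GoldExample
from .model import OntologyTerm, VariantDescriptor
from .ontology import Lexicon, RsidTable

SEX_CELLS = ("XX_diseased", "XX_healthy", "XY_diseased", "XY_healthy")


class DesignError(ValueError):
    """Design parameters outside their valid ranges."""


@dataclass
class MarkerDesign:
    descriptor: VariantDescriptor
    carrier_freq_female_diseased: float
    male_female_carrier_ratio: float

    @property
    def is_x_linked(self) -> bool:
        return self.descriptor.reference_name == "X"

    def cell_freq(self, sex: str, diseased: bool) -> float:
        f = self.carrier_freq_female_diseased
        if diseased and sex == "XY":
            return self.male_female_carrier_ratio * f
        return f


@dataclass
class CohortDesign:
    n_individuals: int
    sex_ratio: float  # fraction XY
    disease: OntologyTerm
    prevalence: float
    markers: list[MarkerDesign]
    seed: int

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise DesignError("n_individuals must be > 0")
        if not 0 < self.sex_ratio < 1:
            raise DesignError("sex_ratio must be in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise DesignError("prevalence must be in (0, 1)")
        for m in self.markers:
            if not 0 < m.carrier_freq_female_diseased < 1:
                raise DesignError(
                    f"{m.descriptor.rsid}: carrier_freq_female_diseased must "
                    "be in (0, 1)"
                )
            if m.male_female_carrier_ratio <= 0:
                raise DesignError(
                    f"{m.descriptor.rsid}: male_female_carrier_ratio must be > 0"
                )
            scaled = m.male_female_carrier_ratio * m.carrier_freq_female_diseased
            if not 0 < scaled < 1:
                raise DesignError(
                    f"{m.descriptor.rsid}: scaled male carrier frequency "
                    f"{scaled:.3f} outside (0, 1)"
                )


@dataclass
class TruthRecord:
    """Realized counts, recomputable exactly from the emitted files."""

    seed: int
    n_individuals: int
    realized_prevalence: float
    #: marker rsid → cell name → {"carriers": int, "total": int}
    marker_cells: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_individuals": self.n_individuals,
            "realized_prevalence": self.realized_prevalence,
            "marker_cells": self.marker_cells,
        }


def ppmi_emulation_preset(n: int = 2000, seed: int = 7) -> CohortDesign:
    """The packaged two-marker preset behind the worked example.

    rs28602900 on X with male:female carrier ratio 1.0 (no sex
    difference) and rs356181 on chromosome 4 with ratio 1.4 among
    diseased individuals; Parkinson's disease as the condition.
    """
    rsids = RsidTable.packaged()
    lexicon = Lexicon.packaged()
    disease = lexicon.entries["parkinsons disease"][0]
    return CohortDesign(
        n_individuals=n,
        sex_ratio=0.6,
        disease=disease,
        prevalence=0.6,
        markers=[
            MarkerDesign(
                descriptor=rsids.entries["rs28602900"],
                carrier_freq_female_diseased=0.25,
                male_female_carrier_ratio=1.0,
            ),
            MarkerDesign(
                descriptor=rsids.entries["rs356181"],
                carrier_freq_female_diseased=0.25,
                male_female_carrier_ratio=1.4,
            ),
        ],
        seed=seed,
    )


def _vcf_text(design: CohortDesign, ids: list[str], dosages: np.ndarray) -> str:
    contigs = []
    for m in design.markers:
        c = m.descriptor.reference_name
        if c not in contigs:
            contigs.append(c)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=nlbeacon-synth",
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids)
    )
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for mi, m in enumerate(design.markers):
        d = m.descriptor
        row = [
            d.reference_name,
            str(d.start + 1),  # VCF POS is 1-based
            d.rsid or ".",
            d.reference_bases,
            d.alternate_bases,
            ".",
            "PASS",
            ".",
            "GT",
        ]
        row += [gt_code[int(x)] for x in dosages[mi]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def generate_cohort(
    design: CohortDesign, out_dir: str | Path, basename: str = "cohort"
) -> tuple[Path, Path, TruthRecord]:
    """Emit a VCF + phenotype CSV (+ truth JSON) for a design.

    Returns the two file paths and the realized-count bookkeeping.  The
    emitted files load back through ``engine.load_cohort`` without
    warnings.
    """
    design.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals

    ids = [f"IND{i + 1:05d}" for i in range(n)]
    is_xy = rng.random(n) < design.sex_ratio
    diseased = rng.random(n) < design.prevalence
    sexes = np.where(is_xy, "XY", "XX")

    dosages = np.zeros((len(design.markers), n), dtype=int)
    truth = TruthRecord(
        seed=design.seed,
        n_individuals=n,
        realized_prevalence=float(diseased.mean()),
    )
    for mi, marker in enumerate(design.markers):
        freqs = np.array(
            [marker.cell_freq(s, d) for s, d in zip(sexes, diseased)]
        )
        carrier = rng.random(n) < freqs
        hom = rng.random(n) < 0.5  # dosage 2 with prob 1/2 when allowed
        dose = np.where(carrier, np.where(hom, 2, 1), 0)
        if marker.is_x_linked:
            dose = np.where(is_xy, np.minimum(dose, 1), dose)  # hemizygous
        dosages[mi] = dose
        cells: dict[str, dict[str, int]] = {}
        for cell in SEX_CELLS:
            sex, status = cell.split("_")
            mask = (sexes == sex) & (diseased == (status == "diseased"))
            cells[cell] = {
                "carriers": int(carrier[mask].sum()),
                "total": int(mask.sum()),
            }
        truth.marker_cells[marker.descriptor.rsid] = cells

    vcf_path = out_dir / f"{basename}.vcf"
    vcf_path.write_text(_vcf_text(design, ids, dosages), encoding="utf-8")

    csv_lines = ["individual_id,karyotypic_sex,conditions"]
    for i, ind_id in enumerate(ids):
        cond = design.disease.curie if diseased[i] else ""
        csv_lines.append(f"{ind_id},{sexes[i]},{cond}")
    csv_path = out_dir / f"{basename}.phenotypes.csv"
    csv_path.write_text("\n".join(csv_lines) + "\n", encoding="utf-8")

    truth_path = out_dir / f"{basename}.truth.json"
    truth_path.write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return vcf_path, csv_path, truth


# ---------------------------------------------------------------------------
# gold extraction sets

_ENTITY_WORDS = ("individuals", "people", "patients")
_COLLECTION_IDS = ("PPMI", "COH001", "STUDY9", "NEURO22")

_FAMILIES = (
    "full_variant",
    "boolean_phenotype",
    "record_variant",
    "count_phenotype",
    "partial_input",
    "distractor",
)


def _unambiguous_conditions(lexicon: Lexicon) -> list[tuple[str, str]]:
    """(display text, curie) pairs for single-candidate lexicon phrases.

    The display text is the term label when it normalizes back to the
    lexicon phrase (so utterances exercise possessives like
    "Parkinson's disease"), else the phrase itself.
    """
    from .ontology import normalize_phrase

    out = []
    seen = set()
    for phrase, cands in lexicon.entries.items():
        if len(cands) != 1 or cands[0].curie in seen:
            continue
        label = cands[0].label
        display = label if label and normalize_phrase(label) == phrase else phrase
        out.append((display, cands[0].curie))
        seen.add(cands[0].curie)
    return out


def _make_example(
    family: str, rng: np.random.Generator, conditions, rsids
) -> GoldExample:
    entity = _ENTITY_WORDS[rng.integers(len(_ENTITY_WORDS))]
    cid = _COLLECTION_IDS[rng.integers(len(_COLLECTION_IDS))]
    label, curie = conditions[rng.integers(len(conditions))]
    rsid = rsids[rng.integers(len(rsids))]
    scope = {
        "collection_scope": "cohort",
        "collection_id": cid,
        "entity_type": "individuals",
    }
    filt = [{"curie": curie, "applies_to": "individuals"}]

    if family == "full_variant":
        return GoldExample(
            utterance=(
                f"How many {entity} in cohort {cid} have {label} "
                f"and a mutation in {rsid}?"
            ),
            gold={
                "scope": scope,
                "granularity": "count",
                "variants": [rsid],
                "filters": filt,
            },
            tags=[family],
        )
    if family == "boolean_phenotype":
        return GoldExample(
            utterance=f"Are there any {entity} in cohort {cid} with {label}?",
            gold={
                "scope": scope,
                "granularity": "boolean",
                "variants": [],
                "filters": filt,
            },
            tags=[family, "skip_eligible"],
        )
    if family == "record_variant":
        return GoldExample(
            utterance=(
                f"List the {entity} in dataset {cid} carrying a variant at {rsid}."
            ),
            gold={
                "scope": {
                    "collection_scope": "dataset",
                    "collection_id": cid,
                    "entity_type": "individuals",
                },
                "granularity": "record",
                "variants": [rsid],
                "filters": [],
            },
            tags=[family],
        )
    if family == "count_phenotype":
        return GoldExample(
            utterance=f"How many {entity} in cohort {cid} have {label}?",
            gold={
                "scope": scope,
                "granularity": "count",
                "variants": [],
                "filters": filt,
            },
            tags=[family, "skip_eligible"],
        )
    if family == "partial_input":
        # No scope is extractable, so the filter's applies_to is unknown too.
        return GoldExample(
            utterance=f"How many have {label}?",
            gold={
                "scope": None,
                "granularity": "count",
                "variants": [],
                "filters": [{"curie": curie, "applies_to": None}],
            },
            tags=[family, "skip_eligible"],
        )
    # distractor: nothing extractable, nothing gold
    return GoldExample(
        utterance="Hello there, hope the weather is nice today.",
        gold={"scope": None, "granularity": None, "variants": [], "filters": []},
        tags=[family, "distractor", "skip_eligible"],
    )


def generate_gold_set(
    n: int,
    seed: int,
    lexicon: Lexicon | None = None,
    rsid_table: RsidTable | None = None,
) -> list[GoldExample]:
    """Sample ``n`` gold examples from parameterized utterance templates.

    Template families cycle round-robin (so all appear once n >= 6) with
    parameters drawn from the same lexicons the rule backend reads;
    deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    lexicon = lexicon or Lexicon.packaged()
    rsid_table = rsid_table or RsidTable.packaged()
    rng = np.random.default_rng(seed)
    conditions = _unambiguous_conditions(lexicon)
    rsids = sorted(rsid_table.entries)
    examples = [
        _make_example(_FAMILIES[i % len(_FAMILIES)], rng, conditions, rsids)
        for i in range(n)
    ]
    order = rng.permutation(n)
    return [examples[i] for i in order]
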