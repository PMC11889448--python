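# Methods

## Query model

The data model is a minimal Beacon-v2-style dialect. A query carries a
collection scope (`cohort` | `dataset`) and id, an entity type
(`individuals`, `biosamples`, `runs`, `analyses`, `g_variants`), a
response granularity (`boolean` < `count` < `record`), ontology filters
and variant descriptors. Filters combine with AND only — the worked
use-case (disease AND variant) needs nothing else, and OR/NOT logic is
deliberately out of scope. Coordinates are 0-based inclusive start
internally (the protocol convention); 1-based VCF positions are
converted at load time, and `chr`-prefixed chromosome labels are
normalized with a warning.

Serialization is canonical by construction: enum values are lower-case
snake tokens parsed case-sensitively, JSON keys are sorted, filter and
variant lists are kept sorted (by CURIE and by coordinate key), and
empty lists serialize as empty arrays rather than omitted keys. Equal
queries therefore produce byte-identical JSON and
`parse_query(serialize_query(q)) == q` holds for every valid query.
Duplicated filters are retained at construction so validation can report
them; `validate_query` never raises — arbitrarily partial input yields a
report listing every missing required field and every constraint
violation. JSON-Schema documents for the request/response shapes ship
under `src/nlbeacon/schemas/` as interface documentation.

## Ontology resolution

Phrase→term and rsID→coordinate lookups run against packaged, versioned
JSON lexicons; there are no live terminology-service calls (hermetic,
and real SNOMED distribution is licensed). Normalization lower-cases,
strips possessive apostrophes and token-edge punctuation, and collapses
whitespace. Matching is longest-match-wins over token spans, ties broken
by earliest position, then lexicon order. A phrase with several
candidate terms is returned as *ambiguous*, never auto-resolved: the
confirm-with-user step owns that decision. The packaged fixture files
are marked `synthetic-fixture-1.0`; only the chromosome assignments of
the two worked-example markers (rs28602900 on X, rs356181 on 4) are
meaningful — positions and alleles are synthetic placeholders.

## Cohort engine

`load_cohort` reads genotypes through cyvcf2 and phenotypes through
pandas, reconciling sample ids by exact match (individuals present in
only one source are dropped with a warning; duplicates are load errors
naming file and line). Multi-allelic records are split into bi-allelic
sites so a site key is always (chromosome, start, ref, alt). Missing
genotypes count as dosage 0 — a discovery engine should not impute.

Query semantics: an individual matches when it carries every filter
CURIE in its condition set and has alternate-allele dosage ≥ 1 at every
listed variant ("mutations in" = carrier status; zygosity-specific
predicates are out of scope). Entity types `individuals` and
`g_variants` execute; the other three validate but raise an
unsupported-entity error, keeping schema completeness at the model
layer. Access control *downgrades* rather than rejects: the response is
answered at min(requested, allowed) granularity with `downgraded=True`,
mirroring network practice of answering at the maximum permitted level;
either way no information beyond the user's level leaves the engine.
Record payloads contain only individual id, karyotypic sex and
conditions, sorted by id for deterministic responses.
`carrier_table` (count-level access or better) returns per-stratum
counts of query-satisfying individuals, with zero-count strata included.

## Extraction architectures

Both orchestrators drive the same four extractors. Parallel invokes all
four independently on the (utterance, prior-state) pair and merges each
result; one failure never blocks the other three. Multi-step runs the
fixed chain scope → granularity → variants → filters, feeds prior step
outputs forward, aborts the whole chain at the first failure, and skips
the variants step when the utterance contains no genomic token
(`rs\d+|chr(omosome)?\s*\w+|\bvariant|\bmutation`) — a concrete,
testable instantiation of "pick the suitable next chain". The chain
order follows the component order scope, granularity, variants, filters.

Merging is pure: scalars (scope fields, granularity) are replaced
field-wise by the newest non-empty value — so a clarification turn can
supply just the missing piece — and lists (variants, filters) union
under canonical keys (rsid/coordinate key; CURIE + applies_to), making
repeated merges idempotent. Union rather than replacement was chosen for
filters so multi-turn sessions accumulate constraints.

The rule backend is a deterministic keyword grammar: granularity cues
("how many"/"count", "is/are there"/"any", "list"/"show"/"records"),
entity nouns, `cohort|dataset <ID>` collection references, `rs\d+`
tokens resolved through the rsID table, and lexicon scanning for
filters; earliest occurrence wins, ties broken by pattern length. Its
token cost is the whitespace-token count of the rendered task input
(task label + utterance), reported through the same field an LLM
connector would use for provider counts. The structured context snapshot
is passed out-of-band and not rendered into the counted prompt, so a
task's cost is identical under both architectures and the token
comparison isolates the number of invocations — multi-step costs
strictly less exactly when it skips or aborts, and the same otherwise.

`build_query` requires an extracted entity type and granularity;
collection scope/id default to (`cohort`, configured default) and the
built query is always surfaced for user confirmation. Otherwise it
returns a clarification request naming missing components in chain
order, asking one question per turn (the first missing component).
Sessions are independent states keyed by tab id; the CLI persists them
as JSON files so tabs survive across invocations.

## Guardrails

Analytics code passes two independent layers. The static sanitizer
parses the full syntax tree and rejects the whole script (every
violation reported; no silent rewriting — excision risks semantically
broken code) on: imports outside the allowlist (pandas, numpy,
matplotlib, math, statistics, sys — shipped as an extensible constant),
filesystem access beyond the injected input path and output directory
(direct `open`, fs-flavored modules, IO calls with literal path
arguments), network primitives, process spawning, dynamic
evaluation/reflection, environment or interpreter internals, and
double-underscore names. Rule ids: `parse_error`, `import_violation`,
`fs_access`, `network`, `process_spawn`, `dynamic_eval`, `env_access`,
`dunder_access`. The packaged adversarial suite (29 scripts) covers
every rule id; the template generator's output is verified clean for
every analytics kind.

The sandbox is a separate process with a fresh working directory,
CPU/address-space rlimits and a wall clock, launched with `python -I`
and a scrubbed environment. A runner shim installs interpreter-level
guards before the script runs: `open` is wrapped to confine reads to the
interpreter prefix, the injected table and the work directory, and
writes to the work/output directories; socket constructors are disabled;
`subprocess` is replaced by a stub that keeps the real exception classes
(libraries name them in `except` clauses) but denies every callable; and
`os`'s spawn/exec functions are disabled. Container/namespace isolation
is a deployment option, not a library requirement — the tests probe the
shim directly with sanitization bypassed. Stdout and stderr are captured
verbatim (statuses: ok, error, timeout, killed) and artifacts are
enumerated from the output directory.

Architecturally, no guardrails operation accepts an extraction backend
and no extraction operation accepts cohort data; an import-graph test
enforces the separation statically.

## Evaluation

Scope and granularity are scored as single-label classification — scope
as one joint label (collection scope + entity type), no partial credit,
the simplest defensible convention. Variants and filters are scored as
sets under canonical keys; a filter's effective `applies_to` defaults to
the respective query's entity type on each side. Metrics are
micro-averaged within component over the gold set; the headline
"average F1" is the arithmetic mean of the four component F1s
(F1 = 0 when P + R = 0). Validity rate is the fraction of examples whose
accumulated state builds a query that passes validation. An independent
straight-line recount in the test suite must agree exactly.

## Synthetic data

Individuals are drawn i.i.d.: sex XY with probability `sex_ratio`,
disease with probability `prevalence`, and per-marker carrier status
Bernoulli with a cell frequency — diseased XY individuals get
`ratio × carrier_freq_female_diseased`, every other cell the female
frequency unchanged, so the designed sex effect is disease-specific.
Carrier status is generated directly rather than through allele
frequencies and Hardy–Weinberg because all downstream computation is
carrier-based; autosomal carriers get dosage 1 or 2 with equal
probability, X-linked XY carriers always 1 (hemizygous, written as a
single alternate allele in diploid GT coding). The generator validates
that every scaled frequency stays inside (0, 1). A truth record with
realized per-cell counts is written beside the VCF/CSV and must match a
recount from the emitted files exactly; equal seeds give byte-identical
files.

Preset (`ppmi_emulation_preset`): two markers — rs28602900 on X with
male:female carrier ratio 1.0, rs356181 on chromosome 4 with ratio
1.4 — Parkinson's disease as the condition, n = 2000, prevalence 0.6,
sex ratio 0.6, female-diseased carrier frequency 0.25. The ratios and
chromosome assignments are the preset's defining contrast; prevalence,
sex ratio, cohort size and the 0.25 base frequency are generator
conveniences chosen once to give all four sex×disease cells informative
counts at n = 2000 (expected ≈ 480–720 diseased per sex; scaled male
frequency 0.35 comfortably inside (0, 1)) — they are not estimates of
any real cohort. At these settings the ratio estimator's binomial
standard error is ≈ 0.13, so recovery is asserted within 3 SE.

The gold-set generator cycles six template families (variant+filter
count queries, boolean and count phenotype-only queries, record+variant
queries, partial inputs, distractors) with parameters drawn from the
same lexicons the rule backend reads. That coupling is intentional: the
gold sets measure the extraction/evaluation plumbing, not language
understanding, which is why the rule backend scores F1 = 1.0 on its own
distribution. Phenotype-only and partial families carry no genomic
token and exercise the multi-step skip path (`skip_eligible` tag);
partial gold marks scope as absent and leaves the filter's `applies_to`
unknown, since no entity type is inferable from the utterance.

## What passing tests do and do not show

The simulator emulates exactly one structure — a disease-specific sex
difference in carrier rates for one autosomal marker against an X-linked
null — under independence of individuals and markers. No linkage
disequilibrium, population structure, genotyping error, missingness or
realistic phenotype complexity is modeled, so passing recovery tests
validates the query/counting machinery, not robustness to real cohort
messiness. Likewise the rule backend's perfect extraction scores say
nothing about LLM extraction quality; the evaluation harness exists so
that real connectors can be scored on curated gold sets through the same
interface.

## Numerical and interface choices

* Problem sizes in the default suite: 2000-individual preset recovery,
  500 engine-oracle pairs at cohort size ≤ 50, 100-example architecture
  comparison, 1000 serialization round trips — the full suite runs in
  well under a minute.
* Acceptance reruns derive the simulation seed from the CLI `--seed`
  (kept below 2^31); the recomputed ratio is a fresh binomial draw
  around the designed 1.4.
* Sandbox default limits: 10 s CPU, 4 GiB address space, 30 s wall —
  address space, not RSS, hence the headroom for numpy/matplotlib
  mappings.
* The CLI config format is YAML; unknown keys are rejected by name.
  Exit codes: 0 success, 1 runtime failure, 2 validation/input error,
  3 not-found.
* Filter serialization includes the optional human-readable label so
  round trips preserve it; consumers needing the strict
  `{id, scope}` pair can ignore it.

## Known limitations

Single local node only (no federation), no OR/NOT filter logic, no
range/bracket variant queries, no genotype-specific (hom/het)
predicates, and no bundled LLM connectors — the backend contract,
clarification loop and evaluation harness are the extension points for
all of these.
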