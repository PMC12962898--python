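# Methods

## Extraction model

The unit of observation is one published network-analysis study, represented
as a structured record: study focus (mixture vs. single purified compound),
per-category methodology flags (how metabolites and targets were sourced),
per-category completeness flags, and the raw "key"/"core" lists the study
printed, each with its heading phrase and ordered items.

Eligibility is decided per category by a fixed gate sequence:

1. **focus gate** — single-compound studies leave the *metabolite* census
   only; their target and pathway lists remain eligible;
2. **completeness gate** — categories marked incomplete/unclear are excluded;
3. **heading match** — a list counts only if its normalized heading exactly
   equals a glossary phrase of that category. Exact (not substring) matching
   prevents "non-core targets" from matching "core targets"; glossaries are
   expected to enumerate variants. The shipped glossary is a placeholder and
   should be replaced by the analyst's own;
4. **list selection** — with several matched non-identical lists, the
   smallest (most refined) is taken; identical lists collapse; an equal-size
   tie keeps the first-occurring list and logs a warning;
5. **standardization** — names are case-folded, whitespace-collapsed,
   Greek-transliterated and dash-unified, then unified through the synonym
   map; post-mapping duplicates drop, first occurrence kept;
6. **threshold gate** — standardized lists longer than `max_items`
   (default 30) are excluded as unrefined.

The threshold is applied *after* standardization/deduplication: duplicates
and synonyms are nomenclature artifacts, and the census counts unique
elements. Because the alternative reading (gate on the raw printed length)
is defensible, `dedupe_before_threshold=False` exposes it for sensitivity
checking.

The synonym map is closed over self-aliases at load time, which makes
application idempotent by construction; chained mappings (a canonical that
is an alias of another canonical) and ambiguous aliases are load-time
errors. Unmapped names pass through as their normalized (lower-case) form,
so canonical display casing is only available for elements the map knows.

## Census statistics

Prevalence is the fraction of cohort studies whose standardized list
contains an element; each study counts once per element. Percentages are
rounded half-up to one decimal (`294/465 → 63.2`, `429/880 → 48.8`).
Published tables of this kind are not always internally consistent about
rounding — some printed values match truncation instead — so the exact-value
tests here are restricted to n/N pairs that are round-half-up consistent.
Rank ties break by canonical name ascending, making tables deterministic.

Sensitivity thresholds filter **studies** (list length ≤ k), never truncate
lists: printed key lists carry no intrinsic ranking, and shrinking
denominators (465 → 258 at Top-5) are the observable signature of study
filtering. Cohorts therefore nest across thresholds, which is asserted as a
property.

Stratified analyses compare database-dependent against
experiment/omics-integrated studies, separately for metabolites and targets
(pathways carry no such flag; requesting them is an error). Studies with an
unknown flag stay in the overall cohort but are omitted from both strata,
so stratum sizes sum to at most the overall N.

## Ghost audit

The audit consumes a user-supplied compound–target edge list plus an
in-vivo detection list; it never queries prediction databases. After
canonicalization and (compound, target) deduplication: ghosts are network
compounds absent from the evidence; degrees count distinct targets;
ghost-only targets have ≥ 1 edge and only ghost neighbours (antitone in the
evidence set); core-set comparison reports intersection, asymmetric
differences and Jaccard (defined as 1.0 for two empty sets, matching the
identical-sets convention). The subset mean degree is reported as a float
and its half-up integer; the background mean is taken over evidenced
compounds.

## Synthetic-data generator

The generator emulates the statistical structure the census assumes, not
any real corpus:

* **Element universes** — ranked name lists per category (60 metabolites,
  80 targets, 40 pathways by default). The metabolite top-20 carries a
  configurable flavonoid fraction (default 0.75); ranks just below the
  top-20 remain real, class-mapped compounds so that stochastic boundary
  swaps do not leak anonymous fillers into class-share analyses.
* **Popularity bias** — element weights ∝ 1/rank^s (default s = 1.1).
  Database-dependent studies draw from this law; integrated studies draw
  from `w·popularity + (1−w)·uniform(disease sub-universe)` (default
  w = 0.3, sub-universe = ranks 6–35), which reproduces the qualitative
  stratified signature: hub prevalence falls when empirical data enter.
* **List lengths** — a truncated Poisson body on 1..30 (means 8/12/10 per
  category) plus a uniform tail on 31..40 whose mass equals the configured
  over-threshold rate, so over-length exclusions occur at realistic rates.
* **Draws** — weighted sampling *without replacement* (a study lists
  distinct elements), realized via Efraimidis–Spirakis keys, which is
  distributionally identical to successive renormalized sampling.
* **Eligibility noise** — single-compound, no-recognized-heading and
  incomplete studies are independent Bernoulli events at the emulated
  population's marginal rates (305, 259, 1 of 1,038 for metabolites, etc.).
  An **exact mode** pins the per-category exclusion counts instead, for
  arithmetic fixtures. A configurable fraction of item names (default 0.1)
  is rendered as a known synonym so the standardization path is always
  exercised.
* **Determinism** — one `numpy` generator seeded from the config drives
  every draw; identical configs yield byte-identical corpora on disk.

`expected_prevalence` is the analytic oracle: the probability that a study's
list contains a given element, integrating the exact inclusion probability
of the successive weighted draw (dynamic programme over subsets of the
non-target support, used when the support has ≤ 18 elements) over the
list-length law; larger supports fall back to seeded Monte Carlo. It
describes the sampling law only — eligibility gates are not applied — so
recovery tests pair it with gate-free configurations.

Pinned fixtures (`table1_fixture`, `table2_fixture`, `top5_fixture`)
construct corpora whose cohort arithmetic and top-element counts equal the
published headline values exactly, by assigning element memberships to
randomly chosen included studies and padding with per-study unique fillers
(count 1 each, so they never perturb rankings). `taohong_fixture` embeds
the published ghost degree profile (223, 125, 119, 118, 109), evidenced
phenolic constituents with modest degrees, a hub target reachable only
through ghosts, and the two published five-element core sets; everything
not pinned by those numbers is synthetic, as the original edge lists are
not public.

### What passing tests do and do not show

The generator reproduces the *mechanisms* the census is designed to
measure — popularity bias, its mitigation by integration, eligibility
noise, nomenclature variation — under ideal conditions: headings match the
glossary exactly or not at all, synonyms are drawn from the shipped map,
and element draws are independent across studies. Real literature has
fuzzy headings, unlisted synonyms, correlated reporting and disease-area
structure none of which are modeled; green tests certify the pipeline's
arithmetic and invariants, not the field-level estimates themselves.

## Numerical and design choices

* Percentages use exact `Decimal` arithmetic before half-up quantization,
  avoiding float boundary artifacts at values like 48.75.
* Corpus files are UTF-8 CSV with minimal quoting and `\n` terminators;
  read∘write is the identity and re-serialization is byte-identical, which
  the round-trip tests assert. Finding lists are stored long-format
  (one row per item); a rank reset to 1 starts a new list, so multiple
  lists may share a heading.
* Validation collects *all* schema violations with file/row coordinates
  before failing.
* Problem sizes in the test suite (corpora of 8–2,000 studies, 20-seed
  recovery runs, 1,000-corpus conservation sweeps) are chosen so the whole
  suite completes in well under a minute while keeping binomial standard
  errors small enough for 3-SE recovery checks to be meaningful.

## Known limitations

* Heading matching is exact-on-normalized; fuzzy or embedding-based
  matching is out of scope, so glossary coverage determines recall.
* Chemical identity is name-based; structure-based resolution
  (InChI/SMILES) is not attempted.
* Pathway records assume enrichment-plot findings were transcribed into the
  findings table; the package does not read figures.
* The stratified analysis is descriptive, as in the emulated census; no
  between-stratum inference is computed.
* Generator defaults are plausibility choices for the emulated population,
  not estimates of the real literature's generative parameters.
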