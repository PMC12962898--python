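# napcensus

A census pipeline for quantifying **output homogeneity** in
network-pharmacology (network-analysis) literature: the striking tendency of
unrelated studies — different herbs, different diseases — to report the same
narrow set of "key" metabolites (quercetin, kaempferol, luteolin), "core"
targets (AKT1, TNF, EGFR) and canonical pathways (PI3K-Akt, AGE-RAGE).

It is written for meta-researchers auditing this literature. Given structured
per-study extraction records, the package:

* identifies each study's key-element lists via an *a priori* glossary of
  heading phrases ("key targets", "core targets", "hub genes", …),
* standardizes nomenclature through a synonym map ("Sophoretin",
  "Meletin" → "Quercetin") and deduplicates,
* builds per-category eligibility cohorts with a full exclusion ledger
  (single-compound studies, no recognized heading, list longer than the
  30-item threshold, incomplete data),
* computes prevalence rankings, threshold-sensitivity analyses (Top-30/20/10/5),
  database-dependent vs. experiment/omics-integrated stratified analyses and
  chemical-class shares, and
* audits compound–target networks for **chemical ghosts** — database-derived
  compounds with no in-vivo detection evidence — their inflated target
  degrees, and *ghost-only targets* that enter a network solely through them.

A synthetic-corpus generator (popularity-biased Zipf draws, with
methodology-dependent mixing toward disease-specific elements) provides
download-free, fully seeded test data with known ground truth.

## The statistic

For element *e* and category cohort *C* (size *N*), prevalence is

```
prev(e) = n_e / N,   n_e = #{ studies in C whose standardized key list contains e }
```

reported as a one-decimal percentage (round half-up). A study counts each
element at most once; cohorts at threshold *k* keep only studies whose
standardized list has ≤ *k* elements, so cohorts nest as *k* shrinks. The
ghost audit reports per-compound distinct-target degrees, subset means
(half-up integer), ghost-only targets, and Jaccard overlap between candidate
core-target sets.

## Worked example

Simulate the pinned census fixture and run the census through the CLI:

```bash
napcensus --preset table1 --seed 1 --out-dir out simulate census
```

which logs

```
INFO napcensus: simulated 1038 studies (table1 preset) -> out
INFO napcensus: metabolite cohort: N=465
INFO napcensus: target cohort: N=880
INFO napcensus: pathway cohort: N=917
```

and writes `out/summary.json` containing, for metabolites,

```json
"metabolite": {
  "N": 465,
  "excluded": {
    "exceeds_threshold": 8,
    "incomplete_data": 1,
    "no_matching_heading": 259,
    "single_compound_study": 305
  }
}
```

— of 1,038 studies, 305 investigated a single purified compound, 259 printed
no list under a recognized heading, 8 reported more than 30 metabolites and 1
was incomplete, leaving a 465-study metabolite cohort — and the top
prevalence row

```json
{"rank": 1, "element": "Quercetin", "n": 294, "N": 465, "percent": 63.2}
```

i.e. quercetin appears as a key metabolite in 63.2% of eligible studies.
Prevalence tables, exclusion ledgers and a manifest (config hash, seed,
input checksums) land beside the summary. The same pipeline is available as
a library (`napcensus.build_cohort`, `prevalence`, `sensitivity`,
`stratify`, `class_share`, `audit_network`, …).

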