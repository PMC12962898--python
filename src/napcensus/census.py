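"""Cohort construction, prevalence rankings, sensitivity and stratification.

The census asks, for each analytical level (metabolite / target / pathway):
in what fraction of eligible studies does each canonical element appear in
the study's key-element list?  Prevalence is reported as ``n/N`` with a
percentage rounded half-up to one decimal; every study counts an element at
most once.  Around that core sit:

* an exclusion ledger per category — the corpus partitioned into the
  included cohort and the studies excluded by each gate, so the cohort
  arithmetic is auditable;
* sensitivity analysis — the cohort restricted to studies reporting at most
  k elements (k = 30, 20, 10, 5 by default), with a rank-stability matrix.
  The threshold filters *studies* by list length; it never truncates lists,
  which carry no intrinsic ranking;
* stratified analysis — prevalence compared between database-dependent and
  experiment/omics-integrated studies (flags are per category; studies with
  an unknown flag stay in the overall cohort but are omitted from both
  strata);
* chemical-class shares — e.g. the fraction of flavonoids among the top-20
  metabolites.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .corpus import (
    CATEGORIES,
    ArticleRecord,
    Category,
    ClassMap,
    Corpus,
    Glossary,
    MetaboliteMethod,
    SynonymMap,
    TargetMethod,
    UNCLASSIFIED,
)
from .extraction import (
    Exclusion,
    ExclusionReason,
    StudyFindings,
    extract_study_findings,
)

logger = logging.getLogger(__name__)

OVERALL = "overall"
DATABASE_DEPENDENT = "database_dependent"
INTEGRATED = "integrated"


def round_half_up(value: Decimal | float, ndigits: int = 0) -> float:
    """Round half away from zero at *ndigits* decimals (873.85 → 873.9)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(n: int, total: int) -> float:
    """Prevalence percentage, round-half-up to one decimal (294/465 → 63.2)."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return float((Decimal(n) * 100 / Decimal(total))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortLedger:
    """Partition of a corpus into one category's cohort and its exclusions."""

    category: Category
    max_items: int
    included_ids: frozenset[str]
    excluded: Mapping[ExclusionReason, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "included_ids", frozenset(self.included_ids))
        object.__setattr__(self, "excluded", {
            r: frozenset(ids) for r, ids in self.excluded.items()
        })

    @property
    def N(self) -> int:
        return len(self.included_ids)

    @property
    def total(self) -> int:
        return self.N + sum(len(v) for v in self.excluded.values())

    def exclusion_counts(self) -> dict[str, int]:
        return {r.value: len(self.excluded.get(r, frozenset()))
                for r in ExclusionReason}

    def check_partition(self, corpus_ids: Sequence[str]) -> None:
        """Assert conservation: included ∪ excluded = corpus, all disjoint."""
        parts = [self.included_ids, *self.excluded.values()]
        union: set[str] = set()
        for p in parts:
            if union & p:
                raise AssertionError("ledger parts are not disjoint")
            union |= p
        if union != set(corpus_ids):
            raise AssertionError("ledger does not partition the corpus")


FindingsCache = dict[str, tuple[str, ...]]  # article_id -> standardized list


def build_cohort(
    corpus: Corpus,
    category: Category,
    glossary: Glossary,
    synonyms: SynonymMap,
    max_items: int = 30,
    dedupe_before_threshold: bool = True,
) -> tuple[CohortLedger, FindingsCache]:
    """Classify every record and return the ledger plus the per-study
    standardized lists of the included studies."""
    category = Category(category)
    included: set[str] = set()
    excluded: dict[ExclusionReason, set[str]] = {r: set() for r in ExclusionReason}
    cache: FindingsCache = {}
    for record in corpus:
        sf = extract_study_findings(
            record, glossary, synonyms, max_items=max_items,
            dedupe_before_threshold=dedupe_before_threshold,
        )
        out = sf.outcomes[category]
        if isinstance(out, Exclusion):
            excluded[out.reason].add(record.article_id)
        else:
            included.add(record.article_id)
            cache[record.article_id] = out
    ledger = CohortLedger(category, max_items, frozenset(included),
                          {r: frozenset(v) for r, v in excluded.items()})
    ledger.check_partition(corpus.ids)
    return ledger, cache


# --------------------------------------------------------------------------
# prevalence
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceRow:
    element: str
    n: int
    N: int
    percent: float
    rank: int


@dataclass(frozen=True)
class PrevalenceTable:
    category: Category
    stratum: str  # overall | database_dependent | integrated
    threshold: int
    rows: tuple[PrevalenceRow, ...]

    def row_for(self, element: str) -> PrevalenceRow | None:
        for row in self.rows:
            if row.element == element:
                return row
        return None

    @property
    def N(self) -> int:
        return self.rows[0].N if self.rows else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rank, r.element, r.n, r.N, r.percent) for r in self.rows],
            columns=["rank", "element", "n", "N", "percent"],
        )


def prevalence(
    cache: FindingsCache,
    ledger: CohortLedger,
    top_n: int | None = None,
    stratum: str = OVERALL,
    ids: frozenset[str] | None = None,
) -> PrevalenceTable:
    """Ranked element counts over the cohort (or the ``ids`` sub-cohort).

    Each study contributes each element at most once; rows are ordered by
    (count descending, canonical name ascending) with 1-based ranks; zero
    counts are never emitted.
    """
    cohort = ledger.included_ids if ids is None else frozenset(ids)
    if ids is not None and not cohort <= ledger.included_ids:
        raise ValueError("ids must be a subset of the ledger's included ids")
    N = len(cohort)
    counts: Counter[str] = Counter()
    for aid in cohort:
        counts.update(set(cache[aid]))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ordered = ordered[:top_n]
    rows = tuple(
        PrevalenceRow(element, n, N, percent(n, N), rank)
        for rank, (element, n) in enumerate(ordered, start=1)
    )
    return PrevalenceTable(ledger.category, stratum, ledger.max_items, rows)


# --------------------------------------------------------------------------
# sensitivity analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityReport:
    category: Category
    thresholds: tuple[int, ...]
    ledgers: Mapping[int, CohortLedger]
    tables: Mapping[int, PrevalenceTable]
    rank_stability: pd.DataFrame = field(compare=False)


def sensitivity(
    corpus: Corpus,
    category: Category,
    glossary: Glossary,
    synonyms: SynonymMap,
    thresholds: Sequence[int] = (30, 20, 10, 5),
    top_n: int | None = None,
) -> SensitivityReport:
    """Recompute the census at progressively stricter list-length thresholds.

    The threshold-t cohort keeps the studies whose standardized list has at
    most t elements, so cohorts nest: cohort(t1) ⊆ cohort(t2) for t1 ≤ t2.
    """
    thresholds = tuple(int(t) for t in thresholds)
    if len(set(thresholds)) != len(thresholds) or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be distinct positive integers")
    t_max = max(thresholds)
    base_ledger, cache = build_cohort(corpus, category, glossary, synonyms,
                                      max_items=t_max)
    ledgers: dict[int, CohortLedger] = {}
    tables: dict[int, PrevalenceTable] = {}
    for t in sorted(thresholds, reverse=True):
        kept = frozenset(aid for aid in base_ledger.included_ids
                         if len(cache[aid]) <= t)
        dropped = base_ledger.included_ids - kept
        excluded = {r: ids for r, ids in base_ledger.excluded.items()}
        excluded[ExclusionReason.EXCEEDS_THRESHOLD] = (
            excluded.get(ExclusionReason.EXCEEDS_THRESHOLD, frozenset()) | dropped
        )
        ledger_t = CohortLedger(Category(category), t, kept, excluded)
        ledgers[t] = ledger_t
        tables[t] = prevalence(cache, ledger_t, top_n=top_n)
    elements = sorted({r.element for tab in tables.values() for r in tab.rows})
    matrix = pd.DataFrame(
        {t: {r.element: r.rank for r in tables[t].rows} for t in sorted(thresholds, reverse=True)},
        index=elements,
    )
    matrix.index.name = "element"
    return SensitivityReport(Category(category), tuple(sorted(thresholds, reverse=True)),
                             ledgers, tables, matrix)


# --------------------------------------------------------------------------
# stratified analysis
# --------------------------------------------------------------------------

_STRATA = {
    Category.METABOLITE: (
        "metabolite_method",
        {MetaboliteMethod.DATABASE_ONLY: DATABASE_DEPENDENT,
         MetaboliteMethod.EXPERIMENTAL_INTEGRATED: INTEGRATED},
        MetaboliteMethod.UNKNOWN,
    ),
    Category.TARGET: (
        "target_method",
        {TargetMethod.DATABASE_ONLY: DATABASE_DEPENDENT,
         TargetMethod.OMICS_INTEGRATED: INTEGRATED},
        TargetMethod.UNKNOWN,
    ),
}


@dataclass(frozen=True)
class StratifiedReport:
    category: Category
    flag_field: str
    tables: Mapping[str, PrevalenceTable]  # stratum label -> table
    n_unknown: int
    prevalence_difference: Mapping[str, float] = field(compare=False)
    """Per-element prevalence difference (database − integrated), in
    percentage points, over elements present in either stratum."""


def stratify(
    corpus: Corpus,
    category: Category,
    flag_field: str,
    glossary: Glossary,
    synonyms: SynonymMap,
    max_items: int = 30,
    top_n: int | None = None,
) -> StratifiedReport:
    """Prevalence tables over the database-dependent vs. integrated strata."""
    category = Category(category)
    if category not in _STRATA:
        raise ValueError(f"no methodology flag defined for {category.value} "
                         "studies; stratification applies to metabolites and "
                         "targets only")
    expected_field, labels, unknown = _STRATA[category]
    if flag_field != expected_field:
        raise ValueError(f"flag_field for {category.value} must be "
                         f"{expected_field!r}, got {flag_field!r}")
    ledger, cache = build_cohort(corpus, category, glossary, synonyms,
                                 max_items=max_items)
    by_record = {r.article_id: getattr(r, flag_field) for r in corpus}
    strata_ids = {label: set() for label in labels.values()}
    n_unknown = 0
    for aid in ledger.included_ids:
        flag = by_record[aid]
        if flag == unknown:
            n_unknown += 1
        else:
            strata_ids[labels[flag]].add(aid)
    if n_unknown:
        logger.info("stratify(%s): %d included studies with unknown %s "
                    "omitted from both strata", category.value, n_unknown,
                    flag_field)
    tables = {
        label: prevalence(cache, ledger, top_n=top_n, stratum=label,
                          ids=frozenset(ids))
        for label, ids in strata_ids.items()
    }
    db, integ = tables[DATABASE_DEPENDENT], tables[INTEGRATED]
    elements = sorted({r.element for r in db.rows} | {r.element for r in integ.rows})
    diffs = {}
    for element in elements:
        p_db = (db.row_for(element).percent if db.row_for(element) else 0.0)
        p_in = (integ.row_for(element).percent if integ.row_for(element) else 0.0)
        diffs[element] = round(p_db - p_in, 1)
    return StratifiedReport(category, flag_field, tables, n_unknown, diffs)


# --------------------------------------------------------------------------
# chemical-class shares
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassShare:
    top_k: int
    counts: Mapping[str, int]
    focal_class: str
    share: float


def class_share(
    table: PrevalenceTable,
    classes: ClassMap,
    focal_class: str = "flavonoid",
    top_k: int = 20,
) -> ClassShare:
    """Chemical-class composition of the top-k rows of a prevalence table.

    ``share`` is the fraction of the focal class among the top-k elements
    (or among all rows when the table is shorter than k).
    """
    if top_k < 1:
        raise ValueError("top_k must be positive")
    top = table.rows[:top_k]
    counts: Counter[str] = Counter(classes.class_of(r.element) for r in top)
    denom = min(top_k, len(table.rows))
    share = counts.get(focal_class, 0) / denom if denom else 0.0
    return ClassShare(top_k, dict(counts), focal_class, share)


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------


def _table_filename(table: PrevalenceTable) -> str:
    return f"prevalence_{table.category.value}_{table.stratum}_{table.threshold}.csv"


def render_report(
    tables: Sequence[PrevalenceTable],
    ledgers: Mapping[Category, CohortLedger],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
    extras: Mapping | None = None,
) -> dict:
    """Write delimited tables, exclusion ledgers and a machine-readable
    summary; returns the summary dict.

    Outputs: ``prevalence_{category}_{stratum}_{threshold}.csv`` per table,
    ``ledger_{category}.csv`` per ledger, ``summary.json`` (cohort Ns,
    exclusion counts, top-3 per table) and ``run.log`` (config hash + seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for table in tables:
        table.to_frame().to_csv(out_dir / _table_filename(table), index=False)
    for category, ledger in ledgers.items():
        rows = [(aid, "included") for aid in sorted(ledger.included_ids)]
        for reason in ExclusionReason:
            rows.extend((aid, reason.value)
                        for aid in sorted(ledger.excluded.get(reason, ())))
        pd.DataFrame(rows, columns=["article_id", "status"]).to_csv(
            out_dir / f"ledger_{Category(category).value}.csv", index=False
        )
    config = dict(config or {})
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    summary = {
        "cohorts": {
            Category(c).value: {"N": led.N, "excluded": led.exclusion_counts()}
            for c, led in ledgers.items()
        },
        "tables": [
            {
                "category": t.category.value,
                "stratum": t.stratum,
                "threshold": t.threshold,
                "N": t.N,
                "top": [
                    {"rank": r.rank, "element": r.element, "n": r.n,
                     "N": r.N, "percent": r.percent}
                    for r in t.rows[:3]
                ],
            }
            for t in tables
        ],
        "config_hash": config_hash,
        "seed": seed,
    }
    if extras:
        summary.update(extras)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    with open(out_dir / "run.log", "a", encoding="utf-8") as fh:
        fh.write(f"config_hash={config_hash} seed={seed} "
                 f"tables={len(tables)} ledgers={len(ledgers)}\n")
    return summary
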