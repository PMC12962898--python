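"""Per-study extraction: heading matching, list selection, standardization.

Turns one :class:`~napcensus.corpus.ArticleRecord` into, per category, either
a standardized key-element list or an explicit exclusion reason.  The gate
order is fixed and mirrors the census eligibility rules:

1. focus gate — single-compound studies are excluded from the *metabolite*
   census only (a study of one purified compound has no key-metabolite list
   worth counting; its targets and pathways still do);
2. completeness gate — categories whose extraction was marked incomplete or
   unclear are excluded;
3. heading match — a list counts only if its heading phrase, normalized,
   exactly equals a glossary phrase of the category (exact match, not
   substring, so "non-core targets" never matches "core targets");
4. list selection — among several matched non-identical lists the smallest,
   most refined one is taken; identical lists collapse;
5. standardization — names are normalized and unified through the synonym
   map, then deduplicated keeping first-occurrence order;
6. threshold gate — lists longer than ``max_items`` (default 30) after
   standardization are excluded as unrefined.

By default the threshold is applied *after* synonym unification and
deduplication: duplicates and synonyms are nomenclature artifacts, and the
census counts unique elements.  Set ``dedupe_before_threshold=False`` to gate
on the raw printed length instead (exposed for sensitivity checking).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .corpus import (
    CATEGORIES,
    ArticleRecord,
    Category,
    FindingList,
    Glossary,
    StudyFocus,
    SynonymMap,
    normalize_name,
)

__all__ = [
    "ExclusionReason", "Exclusion", "StudyFindings", "normalize_name",
    "match_heading", "select_finding_list", "standardize_elements",
    "extract_study_findings", "write_audit",
]

logger = logging.getLogger(__name__)


class ExclusionReason(str, Enum):
    SINGLE_COMPOUND_STUDY = "single_compound_study"
    NO_MATCHING_HEADING = "no_matching_heading"
    EXCEEDS_THRESHOLD = "exceeds_threshold"
    INCOMPLETE_DATA = "incomplete_data"


@dataclass(frozen=True)
class Exclusion:
    reason: ExclusionReason
    detail: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reason", ExclusionReason(self.reason))


Outcome = tuple[str, ...] | Exclusion  # standardized list or exclusion


@dataclass(frozen=True)
class StudyFindings:
    """Per-category outcome for one study: exactly one of a standardized,
    deduplicated element list or an :class:`Exclusion`."""

    article_id: str
    outcomes: dict[Category, Outcome]

    def included(self, category: Category) -> bool:
        return not isinstance(self.outcomes[Category(category)], Exclusion)

    def elements(self, category: Category) -> tuple[str, ...]:
        out = self.outcomes[Category(category)]
        if isinstance(out, Exclusion):
            raise KeyError(f"{self.article_id} excluded for {category}: "
                           f"{out.reason.value}")
        return out


def match_heading(heading: str, glossary: Glossary, category: Category) -> bool:
    """True iff the normalized heading equals a glossary phrase of *category*."""
    return glossary.contains(category, normalize_name(heading))


def select_finding_list(
    matched_lists: Sequence[FindingList],
) -> FindingList | None:
    """Pick the single list to extract from glossary-matched candidates.

    None for empty input; the unique list if one; otherwise the list with
    fewest items (the smaller, more refined set).  Identical lists collapse
    to one.  An equal-size tie between non-identical lists resolves to the
    first-occurring list with a logged warning.
    """
    if not matched_lists:
        return None
    # collapse exact duplicates, keeping first occurrence order
    unique: list[FindingList] = []
    seen: set[tuple] = set()
    for fl in matched_lists:
        key = (fl.category, fl.items)
        if key not in seen:
            seen.add(key)
            unique.append(fl)
    best = min(unique, key=lambda fl: len(fl.items))
    ties = [fl for fl in unique if len(fl.items) == len(best.items)]
    if len(ties) > 1:
        logger.warning(
            "tie between %d non-identical %d-item lists; keeping the "
            "first-occurring one (heading %r)",
            len(ties), len(best.items), ties[0].heading_phrase,
        )
    return ties[0]


def standardize_elements(
    items: Sequence[str], synonyms: SynonymMap
) -> tuple[str, ...]:
    """Normalize and canonicalize raw names, then deduplicate.

    Each item is normalized and mapped through the synonym table when an
    alias is known, otherwise kept as its normalized form.  Post-mapping
    duplicates are removed, keeping first-occurrence order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for raw in items:
        canonical = synonyms.apply(raw)
        key = normalize_name(canonical)
        if key and key not in seen:
            seen.add(key)
            out.append(canonical)
    return tuple(out)


def extract_study_findings(
    record: ArticleRecord,
    glossary: Glossary,
    synonyms: SynonymMap,
    max_items: int = 30,
    dedupe_before_threshold: bool = True,
) -> StudyFindings:
    """Apply the full gate sequence to one record, per category."""
    if max_items < 1:
        raise ValueError("max_items must be positive")
    outcomes: dict[Category, Outcome] = {}
    for category in CATEGORIES:
        outcomes[category] = _extract_category(
            record, category, glossary, synonyms, max_items,
            dedupe_before_threshold,
        )
    return StudyFindings(record.article_id, outcomes)


def _extract_category(
    record: ArticleRecord,
    category: Category,
    glossary: Glossary,
    synonyms: SynonymMap,
    max_items: int,
    dedupe_before_threshold: bool,
) -> Outcome:
    if (category == Category.METABOLITE
            and record.study_focus == StudyFocus.SINGLE_COMPOUND):
        return Exclusion(ExclusionReason.SINGLE_COMPOUND_STUDY,
                         "study of a specific compound")
    if not record.complete[category]:
        return Exclusion(ExclusionReason.INCOMPLETE_DATA,
                         f"{category.value} data incomplete or unclear")
    matched = [fl for fl in record.lists_for(category)
               if match_heading(fl.heading_phrase, glossary, category)]
    selected = select_finding_list(matched)
    if selected is None:
        return Exclusion(ExclusionReason.NO_MATCHING_HEADING,
                         "no list under a glossary-recognized heading")
    standardized = standardize_elements(selected.items, synonyms)
    length = (len(standardized) if dedupe_before_threshold
              else len(selected.items))
    if length > max_items:
        return Exclusion(
            ExclusionReason.EXCEEDS_THRESHOLD,
            f"{length} items > {max_items}-item threshold",
        )
    return standardized


def write_audit(
    findings: Sequence[StudyFindings], path: str | Path
) -> None:
    """Serialize per-study outcomes to a delimited audit file."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(("article_id", "category", "outcome", "n_items", "reason"))
        for sf in findings:
            for category in CATEGORIES:
                out = sf.outcomes[category]
                if isinstance(out, Exclusion):
                    w.writerow((sf.article_id, category.value, "excluded",
                                0, out.reason.value))
                else:
                    w.writerow((sf.article_id, category.value, "included",
                                len(out), ""))
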