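"""Data model and file I/O for network-pharmacology census corpora.

A *corpus* is a set of per-study extraction records from network-analysis
(network-pharmacology) publications.  Each record carries study-level
methodology flags (mixture vs. single-compound focus, database-dependent vs.
experiment/omics-integrated evidence per category) and zero or more raw
*finding lists*: the "key metabolites" / "core targets" / "key pathways"
tables a study printed, exactly as printed.

On disk a corpus is two UTF-8 comma-separated tables:

``studies.csv``
    ``article_id, study_focus, metabolite_method, target_method,
    complete_metabolite, complete_target, complete_pathway``

``findings.csv``
    ``article_id, category, heading_phrase, item_rank, item_name`` — one row
    per listed item.  A new list starts whenever ``item_rank`` resets to 1 or
    the (article, category, heading) key changes; ranks must be contiguous
    within a list.  This long format keeps item order and survives commas or
    quotes inside chemical names via standard CSV quoting.

Configuration assets live beside the corpus: a category-sectioned glossary of
accepted heading phrases (YAML), a two-column synonym map (CSV: alias →
canonical display name) and a two-column chemical-class map (CSV).  All keys
are stored normalized (see :func:`normalize_name`), which makes glossary
matching and synonym application case- and typography-insensitive.
"""

from __future__ import annotations

import csv
import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

SCHEMA_VERSION = "1"
UNCLASSIFIED = "unclassified"


class Category(str, Enum):
    """Analytical level of a finding list."""

    METABOLITE = "metabolite"
    TARGET = "target"
    PATHWAY = "pathway"


CATEGORIES: tuple[Category, ...] = (
    Category.METABOLITE,
    Category.TARGET,
    Category.PATHWAY,
)


class StudyFocus(str, Enum):
    MIXTURE = "mixture"
    SINGLE_COMPOUND = "single_compound"


class MetaboliteMethod(str, Enum):
    """How a study sourced its compound list."""

    DATABASE_ONLY = "database_only"
    EXPERIMENTAL_INTEGRATED = "experimental_integrated"
    UNKNOWN = "unknown"


class TargetMethod(str, Enum):
    """How a study sourced its target list."""

    DATABASE_ONLY = "database_only"
    OMICS_INTEGRATED = "omics_integrated"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """Raised when corpus or configuration files violate the schema.

    Collects *all* violations, each prefixed with its file/row coordinate,
    rather than stopping at the first.
    """

    def __init__(self, errors: Iterable[str]):
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


# --------------------------------------------------------------------------
# name normalization
# --------------------------------------------------------------------------

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
# typographic hyphens/dashes/minus unified to ASCII "-"
_DASHES = "‐‑‒–—―−"
_TRANSLATE = {ord(k): v for k, v in _GREEK.items()}
_TRANSLATE.update({ord(d): "-" for d in _DASHES})


def normalize_name(raw: str) -> str:
    """Normalize a chemical/gene/pathway name or heading phrase.

    Case-folds, strips and collapses whitespace, transliterates Greek letters
    (``β-sitosterol`` → ``beta-sitosterol``) and unifies typographic dashes.
    Total and idempotent: ``normalize_name(normalize_name(x)) ==
    normalize_name(x)`` for any string.
    """
    s = raw.casefold()  # casefold first so Β/μ variants hit the Greek table
    s = s.translate(_TRANSLATE)
    return " ".join(s.split())


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FindingList:
    """One printed list of key elements, as extracted from a study."""

    category: Category
    heading_phrase: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("FindingList.items must be non-empty")
        if any(not str(it).strip() for it in self.items):
            raise ValueError("FindingList.items must be non-blank strings")
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "items", tuple(str(it) for it in self.items))


@dataclass(frozen=True)
class ArticleRecord:
    """One study's metadata, methodology flags and raw finding lists."""

    article_id: str
    study_focus: StudyFocus = StudyFocus.MIXTURE
    metabolite_method: MetaboliteMethod = MetaboliteMethod.UNKNOWN
    target_method: TargetMethod = TargetMethod.UNKNOWN
    complete: Mapping[Category, bool] = field(
        default_factory=lambda: {c: True for c in CATEGORIES}
    )
    finding_lists: tuple[FindingList, ...] = ()

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        object.__setattr__(self, "study_focus", StudyFocus(self.study_focus))
        object.__setattr__(
            self, "metabolite_method", MetaboliteMethod(self.metabolite_method)
        )
        object.__setattr__(self, "target_method", TargetMethod(self.target_method))
        comp = {c: bool(self.complete.get(c, True)) for c in CATEGORIES}
        object.__setattr__(self, "complete", comp)
        object.__setattr__(self, "finding_lists", tuple(self.finding_lists))

    def lists_for(self, category: Category) -> tuple[FindingList, ...]:
        return tuple(fl for fl in self.finding_lists if fl.category == category)

    # complete is a plain dict, so opt the frozen dataclass back into hashing
    # by identity-relevant fields only
    def __hash__(self) -> int:  # pragma: no cover - convenience
        return hash(self.article_id)


@dataclass(frozen=True)
class Provenance:
    source: str = "unknown"
    timestamp: str = ""
    schema_version: str = SCHEMA_VERSION


@dataclass(frozen=True)
class Corpus:
    """A validated collection of :class:`ArticleRecord` with unique ids."""

    records: tuple[ArticleRecord, ...]
    provenance: Provenance = field(default=Provenance(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        dupes = [r.article_id for r in self.records
                 if r.article_id in seen or seen.add(r.article_id)]
        if dupes:
            raise SchemaError([f"duplicate article_id: {d}" for d in dupes])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.article_id for r in self.records)


@dataclass(frozen=True)
class Glossary:
    """Per-category set of normalized heading phrases accepted as 'key'."""

    phrases: Mapping[Category, frozenset[str]]

    def __post_init__(self) -> None:
        errors = []
        norm: dict[Category, frozenset[str]] = {}
        for cat in CATEGORIES:
            raw = self.phrases.get(cat, frozenset())
            ph = frozenset(normalize_name(p) for p in raw)
            if "" in ph:
                errors.append(f"glossary[{cat.value}]: blank phrase after normalization")
                ph = ph - {""}
            norm[cat] = ph
        for i, a in enumerate(CATEGORIES):
            for b in CATEGORIES[i + 1:]:
                for p in sorted(norm[a] & norm[b]):
                    errors.append(
                        f"glossary phrase {p!r} appears in both "
                        f"{a.value} and {b.value}"
                    )
        if errors:
            raise SchemaError(errors)
        object.__setattr__(self, "phrases", norm)

    def contains(self, category: Category, normalized_phrase: str) -> bool:
        return normalized_phrase in self.phrases[Category(category)]


@dataclass(frozen=True)
class SynonymMap:
    """Normalized-alias → canonical display name, idempotent by construction.

    Every canonical's own normalized form is entered as a self-alias, so
    applying the map twice equals applying it once; chains (a canonical that
    is itself an alias of a different canonical) are a load-time error.
    """

    mapping: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   source: str = "synonyms") -> "SynonymMap":
        errors: list[str] = []
        mapping: dict[str, str] = {}
        for i, (alias, canonical) in enumerate(pairs, start=1):
            key = normalize_name(alias)
            canonical = str(canonical).strip()
            if not key or not canonical:
                errors.append(f"{source} row {i}: blank alias or canonical")
                continue
            if key in mapping and mapping[key] != canonical:
                errors.append(
                    f"{source} row {i}: alias {alias!r} mapped to both "
                    f"{mapping[key]!r} and {canonical!r}"
                )
                continue
            mapping[key] = canonical
        # close under self-aliases; detect chains
        for key, canonical in sorted(mapping.items()):
            ckey = normalize_name(canonical)
            if ckey in mapping and mapping[ckey] != canonical:
                errors.append(
                    f"{source}: canonical {canonical!r} (for alias {key!r}) is "
                    f"itself an alias of {mapping[ckey]!r} (chained mapping)"
                )
        if errors:
            raise SchemaError(errors)
        closed = dict(mapping)
        for canonical in mapping.values():
            closed.setdefault(normalize_name(canonical), canonical)
        return cls(closed)

    def apply(self, name: str) -> str:
        """Canonicalize one name: mapped alias → canonical display name,
        unmapped names pass through as their normalized form."""
        key = normalize_name(name)
        return self.mapping.get(key, key)

    def aliases_of(self, canonical: str) -> tuple[str, ...]:
        ckey = normalize_name(canonical)
        return tuple(
            a for a, c in sorted(self.mapping.items())
            if normalize_name(c) == ckey and a != ckey
        )

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class ClassMap:
    """Canonical element name → chemical-class label (e.g. flavonoid).

    Unmapped elements are permitted and report class ``"unclassified"``.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        errors = []
        norm: dict[str, str] = {}
        for element, label in self.mapping.items():
            label = str(label).strip()
            if not label:
                errors.append(f"classmap: blank class label for {element!r}")
                continue
            norm[normalize_name(element)] = label
        if errors:
            raise SchemaError(errors)
        object.__setattr__(self, "mapping", norm)

    def class_of(self, element: str) -> str:
        return self.mapping.get(normalize_name(element), UNCLASSIFIED)


# --------------------------------------------------------------------------
# corpus I/O
# --------------------------------------------------------------------------

STUDIES_COLUMNS = (
    "article_id", "study_focus", "metabolite_method", "target_method",
    "complete_metabolite", "complete_target", "complete_pathway",
)
FINDINGS_COLUMNS = (
    "article_id", "category", "heading_phrase", "item_rank", "item_name",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: str, where: str, errors: list[str]) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    errors.append(f"{where}: invalid boolean {value!r}")
    return True


def _parse_enum(enum_cls, value: str, where: str, errors: list[str]):
    try:
        return enum_cls(value.strip())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        errors.append(f"{where}: invalid value {value!r} (allowed: {allowed})")
        return None


def _check_header(header, expected, path, errors) -> bool:
    if header is None:
        errors.append(f"{path}: empty file (missing header)")
        return False
    if tuple(header) != tuple(expected):
        errors.append(
            f"{path}: unexpected header {header!r}, expected {list(expected)!r}"
        )
        return False
    return True


def read_corpus(studies_path: str | Path, findings_path: str | Path) -> Corpus:
    """Read and validate a two-table corpus.

    Every schema violation is reported (with ``file row N`` coordinates) in a
    single :class:`SchemaError`; a missing file raises ``FileNotFoundError``.
    """
    studies_path = Path(studies_path)
    findings_path = Path(findings_path)
    for p in (studies_path, findings_path):
        if not p.exists():
            raise FileNotFoundError(p)

    errors: list[str] = []
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(studies_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if _check_header(header, STUDIES_COLUMNS, studies_path.name, errors):
            for lineno, row in enumerate(reader, start=2):
                where = f"{studies_path.name} row {lineno}"
                if len(row) != len(STUDIES_COLUMNS):
                    errors.append(f"{where}: expected {len(STUDIES_COLUMNS)} fields, "
                                  f"got {len(row)}")
                    continue
                rec = dict(zip(STUDIES_COLUMNS, row))
                aid = rec["article_id"].strip()
                if not aid:
                    errors.append(f"{where}: blank article_id")
                    continue
                if aid in meta:
                    errors.append(f"{where}: duplicate article_id {aid!r}")
                    continue
                focus = _parse_enum(StudyFocus, rec["study_focus"], where, errors)
                mmeth = _parse_enum(MetaboliteMethod, rec["metabolite_method"],
                                    where, errors)
                tmeth = _parse_enum(TargetMethod, rec["target_method"], where, errors)
                complete = {
                    cat: _parse_bool(rec[f"complete_{cat.value}"], where, errors)
                    for cat in CATEGORIES
                }
                if None in (focus, mmeth, tmeth):
                    continue
                meta[aid] = dict(study_focus=focus, metabolite_method=mmeth,
                                 target_method=tmeth, complete=complete)
                order.append(aid)

    lists: dict[str, list[FindingList]] = {aid: [] for aid in order}
    with open(findings_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if _check_header(header, FINDINGS_COLUMNS, findings_path.name, errors):
            current_key = None
            current_items: list[str] = []
            current_aid = None
            current_cat = None
            current_heading = None
            prev_rank = 0

            def _flush():
                if current_items and current_aid in lists:
                    lists[current_aid].append(
                        FindingList(current_cat, current_heading,
                                    tuple(current_items))
                    )

            for lineno, row in enumerate(reader, start=2):
                where = f"{findings_path.name} row {lineno}"
                if len(row) != len(FINDINGS_COLUMNS):
                    errors.append(f"{where}: expected {len(FINDINGS_COLUMNS)} "
                                  f"fields, got {len(row)}")
                    continue
                aid, cat_raw, heading, rank_raw, item = row
                aid = aid.strip()
                if aid not in meta:
                    errors.append(f"{where}: article_id {aid!r} not present in "
                                  f"{studies_path.name} (orphan findings row)")
                    continue
                cat = _parse_enum(Category, cat_raw, where, errors)
                if cat is None:
                    continue
                try:
                    rank = int(rank_raw)
                    if rank < 1:
                        raise ValueError
                except ValueError:
                    errors.append(f"{where}: invalid item_rank {rank_raw!r}")
                    continue
                if not item.strip():
                    errors.append(f"{where}: blank item_name")
                    continue
                key = (aid, cat, heading)
                if key != current_key or rank == 1:
                    _flush()
                    if rank != 1:
                        errors.append(f"{where}: list must start at item_rank 1, "
                                      f"got {rank}")
                    current_key, current_items = key, []
                    current_aid, current_cat, current_heading = aid, cat, heading
                    prev_rank = 0
                if rank != prev_rank + 1:
                    errors.append(f"{where}: non-contiguous item_rank {rank} "
                                  f"(expected {prev_rank + 1})")
                prev_rank = rank
                current_items.append(item)
            _flush()

    if errors:
        raise SchemaError(errors)

    records = tuple(
        ArticleRecord(article_id=aid, finding_lists=tuple(lists[aid]), **meta[aid])
        for aid in order
    )
    return Corpus(
        records,
        Provenance(source=f"{studies_path.name}+{findings_path.name}"),
    )


def _bool_str(b: bool) -> str:
    return "true" if b else "false"


def _corpus_tables(corpus: Corpus) -> tuple[str, str]:
    """Serialize to (studies_csv, findings_csv) text in the canonical dialect."""
    sbuf = io.StringIO()
    sw = csv.writer(sbuf, lineterminator="\n")
    sw.writerow(STUDIES_COLUMNS)
    fbuf = io.StringIO()
    fw = csv.writer(fbuf, lineterminator="\n")
    fw.writerow(FINDINGS_COLUMNS)
    for r in corpus:
        sw.writerow([
            r.article_id, r.study_focus.value, r.metabolite_method.value,
            r.target_method.value,
            *[_bool_str(r.complete[c]) for c in CATEGORIES],
        ])
        for fl in r.finding_lists:
            for rank, item in enumerate(fl.items, start=1):
                fw.writerow([r.article_id, fl.category.value,
                             fl.heading_phrase, rank, item])
    return sbuf.getvalue(), fbuf.getvalue()


def write_corpus(corpus: Corpus, studies_path: str | Path,
                 findings_path: str | Path) -> None:
    """Write the two delimited tables; ``read_corpus`` of the outputs
    reproduces the input exactly, and re-serialization is byte-identical."""
    studies_csv, findings_csv = _corpus_tables(corpus)
    Path(studies_path).write_text(studies_csv, encoding="utf-8")
    Path(findings_path).write_text(findings_csv, encoding="utf-8")


# --------------------------------------------------------------------------
# configuration assets
# --------------------------------------------------------------------------


def read_glossary(path: str | Path) -> Glossary:
    """Load a category-sectioned YAML glossary: ``{category: [phrases...]}``."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    errors = []
    phrases: dict[Category, frozenset[str]] = {}
    for key, values in data.items():
        try:
            cat = Category(str(key))
        except ValueError:
            errors.append(f"{path}: unknown glossary category {key!r}")
            continue
        if not isinstance(values, list):
            errors.append(f"{path}: glossary section {key!r} must be a list")
            continue
        phrases[cat] = frozenset(str(v) for v in values)
    if errors:
        raise SchemaError(errors)
    return Glossary(phrases)


def _read_two_column(path: str | Path, expected_header: tuple[str, str]):
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        errors: list[str] = []
        if _check_header(header, expected_header, Path(path).name, errors):
            for lineno, row in enumerate(reader, start=2):
                if len(row) != 2:
                    errors.append(f"{Path(path).name} row {lineno}: expected 2 "
                                  f"fields, got {len(row)}")
                    continue
                rows.append(tuple(row))
        if errors:
            raise SchemaError(errors)
    return rows


def read_synonyms(path: str | Path) -> SynonymMap:
    """Load a two-column CSV synonym table (``alias,canonical``)."""
    return SynonymMap.from_pairs(
        _read_two_column(path, ("alias", "canonical")), source=Path(path).name
    )


def read_classmap(path: str | Path) -> ClassMap:
    """Load a two-column CSV class table (``element,class_label``)."""
    return ClassMap(dict(_read_two_column(path, ("element", "class_label"))))


def write_glossary(glossary: Glossary, path: str | Path) -> None:
    data = {c.value: sorted(glossary.phrases[c]) for c in CATEGORIES}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def write_synonyms(synonyms: SynonymMap, path: str | Path) -> None:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(("alias", "canonical"))
    for alias, canonical in sorted(synonyms.mapping.items()):
        w.writerow((alias, canonical))
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_classmap(classmap: ClassMap, path: str | Path) -> None:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(("element", "class_label"))
    for element, label in sorted(classmap.mapping.items()):
        w.writerow((element, label))
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# --------------------------------------------------------------------------
# shipped defaults (placeholders; replace with study-specific assets)
# --------------------------------------------------------------------------

_DEFAULT_GLOSSARY = {
    Category.METABOLITE: frozenset({
        "key metabolites", "core metabolites", "key components",
        "core components", "key compounds", "core compounds",
        "key active ingredients", "main active ingredients",
        "key active components", "key ingredients",
    }),
    Category.TARGET: frozenset({
        "key targets", "core targets", "hub targets", "hub genes",
        "core genes", "key genes", "core protein targets",
    }),
    Category.PATHWAY: frozenset({
        "key pathways", "core pathways", "key signaling pathways",
        "top enriched pathways", "main pathways", "key kegg pathways",
    }),
}

_DEFAULT_SYNONYM_PAIRS = (
    ("Sophoretin", "Quercetin"),
    ("Meletin", "Quercetin"),
    ("Xanthaurine", "Quercetin"),
    ("Robigenin", "Kaempferol"),
    ("Pelargidenolon", "Kaempferol"),
    ("Digitoflavone", "Luteolin"),
    ("Luteoline", "Luteolin"),
    ("β-Sitosterol", "Beta-sitosterol"),
    ("22,23-Dihydrostigmasterol", "Beta-sitosterol"),
    ("Stigmasterin", "Stigmasterol"),
    ("Salipurpol", "Naringenin"),
    ("3'-Methylquercetin", "Isorhamnetin"),
    ("Noroxylin", "Baicalein"),
    ("Coniferic acid", "Ferulic acid"),
    ("Protein kinase B alpha", "AKT1"),
    ("PKB", "AKT1"),
    ("TNF-alpha", "TNF"),
    ("TNFA", "TNF"),
    ("Cachectin", "TNF"),
    ("ERBB1", "EGFR"),
    ("HER1", "EGFR"),
    ("Interleukin-6", "IL6"),
    ("COX-2", "PTGS2"),
    ("COX2", "PTGS2"),
    ("ER-alpha", "ESR1"),
)

_DEFAULT_CLASSES = {
    "flavonoid": (
        "Quercetin", "Kaempferol", "Luteolin", "Naringenin", "Isorhamnetin",
        "Baicalein", "Apigenin", "Wogonin", "Myricetin", "Rutin", "Catechin",
        "Chrysin", "Hesperetin", "Genistein", "Vitexin", "Puerarin",
        "Silibinin", "Hyperoside", "Quercitrin", "Baicalin",
    ),
    "phytosterol": ("Beta-sitosterol", "Stigmasterol"),
    "phenolic acid": ("Ferulic acid", "Vanillic acid", "Gallic acid",
                      "Chlorogenic acid"),
    "triterpenoid": ("Ursolic acid", "Oleanolic acid"),
    "alkaloid": ("Berberine",),
    "carotenoid": ("Beta-carotene",),
}


def default_glossary() -> Glossary:
    """Placeholder heading glossary; real analyses should load their own."""
    return Glossary(_DEFAULT_GLOSSARY)


def default_synonyms() -> SynonymMap:
    """Small PubChem/UniProt-style synonym table for high-frequency elements."""
    return SynonymMap.from_pairs(_DEFAULT_SYNONYM_PAIRS, source="defaults")


def default_classmap() -> ClassMap:
    return ClassMap({
        name: label for label, names in _DEFAULT_CLASSES.items() for name in names
    })
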