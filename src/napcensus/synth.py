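"""Synthetic corpora and networks with the statistical structure the census
assumes.

The generative model emulates a population of network-analysis studies in
which element reporting is *popularity-biased*: each category has a ranked
element universe with Zipf-like weights (weight ∝ 1/rank^s), and a study's
key-element list is a weighted draw without replacement from that universe.
Database-dependent studies draw straight from the popularity law; studies
that integrate experimental component identification or multi-omics data
draw from the mixture ``w·popularity + (1−w)·uniform`` over a
disease-specific sub-universe, which dilutes the hubs — the corpus-level
signature of bias mitigation.  Study-eligibility noise (single-compound
studies, lists under unrecognized headings, over-threshold lists, incomplete
records) is generated at configurable rates, or pinned to exact counts for
arithmetic fixtures.

Draws without replacement use Efraimidis–Spirakis keys (``u**(1/w)``,
top-k), which realizes exactly the successive renormalized-sampling law that
the analytic inclusion-probability oracle (:func:`expected_prevalence`)
integrates in closed form.

The module also builds bipartite compound–target networks in which named
"ghost" compounds carry requested target degrees, plus pinned corpus
fixtures reproducing the printed census arithmetic.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    CATEGORIES,
    ArticleRecord,
    Category,
    Corpus,
    FindingList,
    Glossary,
    MetaboliteMethod,
    Provenance,
    StudyFocus,
    SynonymMap,
    TargetMethod,
    default_glossary,
    default_synonyms,
    normalize_name,
)
from .extraction import ExclusionReason
from .network_audit import BipartiteNetwork, DetectionEvidence

DATABASE = "database"
INTEGRATED = "integrated"

DECOY_HEADINGS = (
    "identified components",
    "network construction",
    "molecular docking results",
    "all predicted targets",
    "enrichment analysis",
)

# ranked name pools for the synthetic universes; ordering mimics the field's
# observed prevalence ranking
_FLAVONOIDS = (
    "Quercetin", "Kaempferol", "Luteolin", "Naringenin", "Isorhamnetin",
    "Baicalein", "Apigenin", "Wogonin", "Myricetin", "Rutin", "Catechin",
    "Chrysin", "Hesperetin", "Genistein", "Vitexin", "Puerarin", "Silibinin",
    "Hyperoside", "Quercitrin", "Baicalin",
)
_NON_FLAVONOIDS = (
    "Beta-sitosterol", "Stigmasterol", "Ursolic acid", "Ferulic acid",
    "Berberine", "Vanillic acid", "Gallic acid", "Oleanolic acid",
    "Chlorogenic acid", "Beta-carotene",
)
_TARGET_NAMES = (
    "AKT1", "TNF", "EGFR", "IL6", "PTGS2", "ESR1", "TP53", "VEGFA", "JUN",
    "STAT3", "MAPK3", "MAPK1", "CASP3", "BCL2", "MYC", "HIF1A", "PPARG",
    "HSP90AA1", "EP300", "SRC",
)
_PATHWAY_NAMES = (
    "AGE-RAGE signaling pathway", "PI3K-Akt signaling pathway",
    "Lipid and atherosclerosis", "Pathways in cancer",
    "TNF signaling pathway", "MAPK signaling pathway",
    "IL-17 signaling pathway", "HIF-1 signaling pathway", "Apoptosis",
    "NF-kappa B signaling pathway",
)


def metabolite_universe(size: int, flavonoid_fraction_top20: float = 0.75
                        ) -> tuple[str, ...]:
    """Ranked metabolite universe whose top-20 contains the requested
    flavonoid fraction (quercetin/kaempferol/luteolin lead, as observed).

    Ranks just below the top stay real, class-mapped compounds — the
    boundary of an observed top-20 is occupied by named phytochemicals, not
    anonymous entries — and deeper ranks fall back to synthetic fillers.
    """
    head_len = min(size, 20)
    n_flav = max(0, min(head_len, math.ceil(20 * flavonoid_fraction_top20)))
    head: list[str] = []
    fi = ni = 0
    for rank in range(head_len):
        take_flav = (math.ceil((rank + 1) * flavonoid_fraction_top20) > fi
                     and fi < len(_FLAVONOIDS) and fi < n_flav)
        if take_flav or ni >= len(_NON_FLAVONOIDS):
            head.append(_FLAVONOIDS[fi]); fi += 1
        else:
            head.append(_NON_FLAVONOIDS[ni]); ni += 1
    leftovers = [n for n in (*_FLAVONOIDS, *_NON_FLAVONOIDS) if n not in head]
    tail = leftovers + [f"Compound-{i:03d}"
                        for i in range(len(head) + len(leftovers) + 1, size + 1)]
    return tuple(head + tail)[:size]


def target_universe(size: int) -> tuple[str, ...]:
    tail = [f"GENE{i:03d}" for i in range(len(_TARGET_NAMES) + 1, size + 1)]
    return tuple(list(_TARGET_NAMES) + tail)[:size]


def pathway_universe(size: int) -> tuple[str, ...]:
    tail = [f"Synthetic pathway {i:03d}"
            for i in range(len(_PATHWAY_NAMES) + 1, size + 1)]
    return tuple(list(_PATHWAY_NAMES) + tail)[:size]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

# emulated study population: 1,038 studies with the observed exclusion
# rates, expressed as marginal per-study probabilities
_N_REF = 1038


def _default_rates() -> dict:
    return {
        Category.METABOLITE: 259 / _N_REF,
        Category.TARGET: 107 / _N_REF,
        Category.PATHWAY: 87 / _N_REF,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the biased-corpus generative model.

    Defaults describe the emulated study population: 1,038 studies, the
    observed exclusion rates, Zipf popularity bias with exponent ``s`` over
    ranked per-category universes, and method-dependent mixing between the
    popularity law and a disease-specific uniform component.
    """

    n_studies: int = _N_REF
    seed: int = 0
    categories: tuple[Category, ...] = CATEGORIES
    universe_sizes: Mapping[Category, int] = field(default_factory=lambda: {
        Category.METABOLITE: 60, Category.TARGET: 80, Category.PATHWAY: 40,
    })
    zipf_exponent: float = 1.1
    flavonoid_fraction_top20: float = 0.75
    # probability a study integrates experimental/omics data, per category
    # (observed stratum shares: 137/465 metabolite, 153/878 target)
    p_integrated: Mapping[Category, float] = field(default_factory=lambda: {
        Category.METABOLITE: 137 / 465, Category.TARGET: 153 / 878,
        Category.PATHWAY: 0.0,
    })
    bias_weight_w: float = 0.3  # integrated draws: w·popularity + (1-w)·uniform
    disease_offset: int = 5
    disease_subuniverse_size: int = 30
    mean_list_length: Mapping[Category, float] = field(default_factory=lambda: {
        Category.METABOLITE: 8.0, Category.TARGET: 12.0, Category.PATHWAY: 10.0,
    })
    over_threshold_rate: Mapping[Category, float] = field(default_factory=lambda: {
        Category.METABOLITE: 8 / _N_REF, Category.TARGET: 49 / _N_REF,
        Category.PATHWAY: 30 / _N_REF,
    })
    threshold: int = 30       # body/tail boundary of the list-length law
    max_list_length: int = 40  # L_max (> threshold so over-length lists occur)
    single_compound_rate: float = 305 / _N_REF
    no_heading_rate: Mapping[Category, float] = field(default_factory=_default_rates)
    incomplete_rate: Mapping[Category, float] = field(default_factory=lambda: {
        Category.METABOLITE: 1 / _N_REF, Category.TARGET: 2 / _N_REF,
        Category.PATHWAY: 4 / _N_REF,
    })
    p_unknown_method: float = 0.0
    alias_rate: float = 0.1  # chance an item is written as a known synonym
    # exact mode: per-category exclusion counts pinned instead of sampled
    exact_counts: Mapping[Category, Mapping[ExclusionReason, int]] | None = None
    glossary: Glossary = field(default_factory=default_glossary, compare=False)
    synonyms: SynonymMap = field(default_factory=default_synonyms, compare=False)

    # -- derived structure -------------------------------------------------

    def universe(self, category: Category) -> tuple[str, ...]:
        category = Category(category)
        size = int(self.universe_sizes[category])
        if category == Category.METABOLITE:
            return metabolite_universe(size, self.flavonoid_fraction_top20)
        if category == Category.TARGET:
            return target_universe(size)
        return pathway_universe(size)

    def popularity_weights(self, category: Category) -> np.ndarray:
        u = len(self.universe(category))
        w = 1.0 / np.arange(1, u + 1) ** self.zipf_exponent
        return w / w.sum()

    def disease_indices(self, category: Category) -> np.ndarray:
        u = len(self.universe(category))
        lo = min(self.disease_offset, u)
        hi = min(lo + self.disease_subuniverse_size, u)
        return np.arange(lo, hi)

    def stratum_weights(self, category: Category, stratum: str) -> np.ndarray:
        pop = self.popularity_weights(category)
        if stratum in (DATABASE, "database_only", "database_dependent"):
            return pop
        if stratum in (INTEGRATED, "experimental_integrated",
                       "omics_integrated"):
            sub = self.disease_indices(category)
            if len(sub) == 0:
                raise ValueError("empty disease sub-universe")
            mix = self.bias_weight_w * pop
            mix[sub] += (1.0 - self.bias_weight_w) / len(sub)
            return mix / mix.sum()
        raise ValueError(f"unknown stratum {stratum!r}")

    def list_length_probs(self, category: Category) -> np.ndarray:
        """pmf over lengths, index = length (index 0 unused, mass 0)."""
        lam = float(self.mean_list_length[Category(category)])
        tail_rate = float(self.over_threshold_rate[Category(category)])
        t, lmax = self.threshold, self.max_list_length
        body_hi = min(t, lmax)
        body = np.array([math.exp(-lam) * lam ** k / math.factorial(k)
                         for k in range(1, body_hi + 1)])
        body = body / body.sum()
        p = np.zeros(lmax + 1)
        if tail_rate > 0 and lmax > t:
            p[1:body_hi + 1] = body * (1.0 - tail_rate)
            p[t + 1:lmax + 1] = tail_rate / (lmax - t)
        else:
            p[1:body_hi + 1] = body
        return p

    def validate(self) -> None:
        probs = [self.single_compound_rate, self.alias_rate,
                 self.bias_weight_w, self.flavonoid_fraction_top20,
                 self.p_unknown_method,
                 *[self.p_integrated[c] for c in self.categories],
                 *[self.no_heading_rate[c] for c in self.categories],
                 *[self.incomplete_rate[c] for c in self.categories],
                 *[self.over_threshold_rate[c] for c in self.categories]]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates/probabilities must lie in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.n_studies < 0:
            raise ValueError("n_studies must be >= 0")
        if self.max_list_length < 1 or self.threshold < 1:
            raise ValueError("list lengths must be >= 1")
        for c in self.categories:
            u = int(self.universe_sizes[Category(c)])
            if self.max_list_length > u:
                raise ValueError(
                    f"infeasible config: max_list_length {self.max_list_length} "
                    f"exceeds the {Category(c).value} universe size {u}"
                )


# --------------------------------------------------------------------------
# weighted sampling without replacement
# --------------------------------------------------------------------------


def weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Draw k distinct indices with successive probability ∝ weight.

    Efraimidis–Spirakis: keys ``u**(1/w)``, take the k largest; the ordered
    result is distributed exactly as sequential renormalized sampling.
    """
    w = np.asarray(weights, dtype=float)
    support = w > 0
    if k > int(support.sum()):
        raise ValueError(
            f"infeasible draw: requested {k} items from a support of "
            f"{int(support.sum())}"
        )
    u = rng.random(len(w))
    with np.errstate(divide="ignore"):
        keys = np.where(support, u ** (1.0 / np.where(support, w, 1.0)), -1.0)
    order = np.argsort(-keys, kind="stable")
    return order[:k]


# --------------------------------------------------------------------------
# corpus generation
# --------------------------------------------------------------------------

_ROLE_CLEAN = "clean"
_ROLE_ORDER = (
    ExclusionReason.SINGLE_COMPOUND_STUDY,
    ExclusionReason.INCOMPLETE_DATA,
    ExclusionReason.NO_MATCHING_HEADING,
    ExclusionReason.EXCEEDS_THRESHOLD,
)


def _exact_roles(rng, n: int, counts: Mapping[ExclusionReason, int]) -> list:
    total = sum(int(counts.get(r, 0)) for r in _ROLE_ORDER)
    if total > n:
        raise ValueError("exact exclusion counts exceed n_studies")
    perm = rng.permutation(n)
    roles = [_ROLE_CLEAN] * n
    pos = 0
    for reason in _ROLE_ORDER:
        c = int(counts.get(reason, 0))
        for i in perm[pos:pos + c]:
            roles[i] = reason
        pos += c
    return roles


def _sample_length(rng, pmf: np.ndarray) -> int:
    return int(rng.choice(len(pmf), p=pmf))


def _alias_pool(synonyms: SynonymMap) -> dict[str, tuple[str, ...]]:
    pool: dict[str, list[str]] = {}
    for alias, canonical in synonyms.mapping.items():
        ckey = normalize_name(canonical)
        if alias != ckey:
            pool.setdefault(ckey, []).append(alias)
    return {k: tuple(sorted(v)) for k, v in pool.items()}


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Draw a corpus from the generative model; deterministic given the seed.

    In rate mode every exclusion trigger is an independent Bernoulli per
    study, so marginal rates converge to the configured values; in exact
    mode (``config.exact_counts``) the per-category exclusion counts are
    pinned and the remaining studies are guaranteed clean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_studies
    provenance = Provenance(source="synthetic", timestamp="")
    if n == 0:
        return Corpus((), provenance)

    ids = [f"S{i + 1:05d}" for i in range(n)]
    aliases = _alias_pool(config.synonyms)
    exact = config.exact_counts is not None

    # per-category role assignment (consumes rng in a fixed order)
    roles: dict[Category, list] = {}
    for category in CATEGORIES:
        if category not in config.categories:
            roles[category] = [None] * n
            continue
        if exact:
            counts = dict(config.exact_counts.get(category, {}))
            if category != Category.METABOLITE:
                counts.pop(ExclusionReason.SINGLE_COMPOUND_STUDY, None)
            roles[category] = _exact_roles(rng, n, counts)
        else:
            cat_roles: list = [_ROLE_CLEAN] * n
            if category == Category.METABOLITE:
                single = rng.random(n) < config.single_compound_rate
            else:
                single = np.zeros(n, dtype=bool)
            incomplete = rng.random(n) < config.incomplete_rate[category]
            no_heading = rng.random(n) < config.no_heading_rate[category]
            for i in range(n):
                if single[i]:
                    cat_roles[i] = ExclusionReason.SINGLE_COMPOUND_STUDY
                elif incomplete[i]:
                    cat_roles[i] = ExclusionReason.INCOMPLETE_DATA
                elif no_heading[i]:
                    cat_roles[i] = ExclusionReason.NO_MATCHING_HEADING
            roles[category] = cat_roles

    universes = {c: config.universe(c) for c in config.categories}
    weights = {
        c: {DATABASE: config.stratum_weights(c, DATABASE),
            INTEGRATED: config.stratum_weights(c, INTEGRATED)}
        for c in config.categories
    }
    pmfs = {c: config.list_length_probs(c) for c in config.categories}
    body_pmfs = {}
    tail_pmfs = {}
    for c in config.categories:
        p = pmfs[c].copy()
        body = p.copy()
        body[config.threshold + 1:] = 0.0
        body_pmfs[c] = body / body.sum()
        tail = p.copy()
        tail[:config.threshold + 1] = 0.0
        if tail.sum() > 0:
            tail_pmfs[c] = tail / tail.sum()
        elif config.max_list_length > config.threshold:
            # exact mode may pin over-threshold studies with a zero tail rate
            t = np.zeros_like(p)
            t[config.threshold + 1:] = 1.0
            tail_pmfs[c] = t / t.sum()
        else:
            tail_pmfs[c] = None

    records = []
    for i, aid in enumerate(ids):
        focus = (StudyFocus.SINGLE_COMPOUND
                 if roles[Category.METABOLITE][i]
                 == ExclusionReason.SINGLE_COMPOUND_STUDY
                 else StudyFocus.MIXTURE)
        complete = {c: True for c in CATEGORIES}
        methods: dict[Category, bool | None] = {}
        lists: list[FindingList] = []
        for category in config.categories:
            role = roles[category][i]
            integrated = bool(rng.random() < config.p_integrated[category])
            methods[category] = integrated
            if role == ExclusionReason.INCOMPLETE_DATA:
                complete[category] = False
            # list length
            if role == ExclusionReason.SINGLE_COMPOUND_STUDY:
                length = 1
            elif role == ExclusionReason.EXCEEDS_THRESHOLD:
                if tail_pmfs[category] is None:
                    raise ValueError(
                        "infeasible config: over-threshold studies requested "
                        "but max_list_length <= threshold")
                length = _sample_length(rng, tail_pmfs[category])
            elif exact:
                length = _sample_length(rng, body_pmfs[category])
            else:
                length = _sample_length(rng, pmfs[category])
            stratum = INTEGRATED if integrated else DATABASE
            idx = weighted_sample_without_replacement(
                rng, weights[category][stratum], length
            )
            universe = universes[category]
            items = []
            for j in idx:
                name = universe[j]
                pool = aliases.get(normalize_name(name))
                if pool and rng.random() < config.alias_rate:
                    name = pool[int(rng.integers(len(pool)))]
                items.append(name)
            heading = (
                DECOY_HEADINGS[int(rng.integers(len(DECOY_HEADINGS)))]
                if role == ExclusionReason.NO_MATCHING_HEADING
                else sorted(config.glossary.phrases[category])[
                    int(rng.integers(len(config.glossary.phrases[category])))]
            )
            lists.append(FindingList(category, heading, tuple(items)))
        mmeth = (MetaboliteMethod.EXPERIMENTAL_INTEGRATED
                 if methods.get(Category.METABOLITE) else
                 MetaboliteMethod.DATABASE_ONLY)
        tmeth = (TargetMethod.OMICS_INTEGRATED
                 if methods.get(Category.TARGET) else
                 TargetMethod.DATABASE_ONLY)
        if config.p_unknown_method:
            if rng.random() < config.p_unknown_method:
                mmeth = MetaboliteMethod.UNKNOWN
            if rng.random() < config.p_unknown_method:
                tmeth = TargetMethod.UNKNOWN
        records.append(ArticleRecord(
            article_id=aid, study_focus=focus, metabolite_method=mmeth,
            target_method=tmeth, complete=complete,
            finding_lists=tuple(lists),
        ))
    return Corpus(tuple(records), provenance)


# --------------------------------------------------------------------------
# analytic inclusion-probability oracle
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedPrevalence:
    element: str
    database: float
    integrated: float


def _successive_inclusion_probs(
    weights: np.ndarray, target: int, max_len: int
) -> np.ndarray:
    """P(target among the first k successive weighted draws), k = 0..max_len.

    Exact dynamic programme over subsets of the non-target support; states
    where the target has been drawn are absorbed into the cumulative
    probability.
    """
    w = np.asarray(weights, dtype=float)
    if w[target] <= 0:
        return np.zeros(max_len + 1)
    others = [i for i in np.flatnonzero(w > 0) if i != target]
    m = len(others)
    total = w[target] + sum(w[i] for i in others)
    ow = [w[i] for i in others]
    p_in = np.zeros(max_len + 1)
    # mask over `others`; value = P(state reached, target not yet drawn)
    level: dict[int, float] = {0: 1.0}
    mask_weight: dict[int, float] = {0: 0.0}
    cum = 0.0
    for k in range(1, max_len + 1):
        nxt: dict[int, float] = {}
        nxt_weight: dict[int, float] = {}
        for mask, prob in level.items():
            denom = total - mask_weight[mask]
            cum += prob * w[target] / denom
            for j in range(m):
                bit = 1 << j
                if mask & bit:
                    continue
                nm = mask | bit
                nxt[nm] = nxt.get(nm, 0.0) + prob * ow[j] / denom
                if nm not in nxt_weight:
                    nxt_weight[nm] = mask_weight[mask] + ow[j]
        p_in[k] = cum
        level, mask_weight = nxt, nxt_weight
        if not level:  # all non-target items exhausted; target certain
            p_in[k:] = 1.0
            break
    return p_in


def expected_prevalence(
    config: SyntheticConfig,
    element: str,
    stratum: str,
    category: Category | None = None,
    method: str = "auto",
    n_mc: int = 20000,
    exact_limit: int = 18,
) -> float:
    """Analytic probability that a study's sampled list contains *element*.

    Integrates the exact inclusion probability of the successive weighted
    without-replacement draw over the configured list-length law.  Exact by
    dynamic programming when the weight support is small (≤ ``exact_limit``);
    otherwise Monte Carlo with ``n_mc`` replicates (seeded from the config).
    Describes the sampling law of a study's list; eligibility gates are not
    applied.
    """
    if category is None:
        for c in config.categories:
            if element in config.universe(c):
                category = c
                break
        else:
            raise KeyError(f"element {element!r} not in any configured universe")
    category = Category(category)
    universe = config.universe(category)
    if element not in universe:
        raise KeyError(f"element {element!r} not in the {category.value} universe")
    target = universe.index(element)
    w = config.stratum_weights(category, stratum)
    pmf = config.list_length_probs(category)
    support = int((w > 0).sum())
    if w[target] <= 0:
        return 0.0
    max_len = min(len(pmf) - 1, support)
    use_exact = method == "exact" or (method == "auto" and support <= exact_limit)
    if use_exact:
        p_in = _successive_inclusion_probs(w, target, max_len)
        total = 0.0
        for length in range(1, len(pmf)):
            if pmf[length] == 0:
                continue
            total += pmf[length] * p_in[min(length, max_len)]
        return total
    # Monte Carlo over the identical sampling law
    rng = np.random.default_rng((config.seed, 0xE5))
    lengths = rng.choice(len(pmf), size=n_mc, p=pmf)
    u = rng.random((n_mc, len(w)))
    with np.errstate(divide="ignore"):
        keys = np.where(w > 0, u ** (1.0 / np.where(w > 0, w, 1.0)), -1.0)
    rank = (keys > keys[:, [target]]).sum(axis=1)
    return float((rank < np.minimum(lengths, support)).mean())


def expected_prevalence_profile(
    config: SyntheticConfig, element: str, category: Category | None = None
) -> ExpectedPrevalence:
    return ExpectedPrevalence(
        element,
        expected_prevalence(config, element, DATABASE, category),
        expected_prevalence(config, element, INTEGRATED, category),
    )


# --------------------------------------------------------------------------
# network generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of a synthetic compound–target network with ghosts."""

    ghost_degrees: Mapping[str, int]
    evidenced_degrees: Mapping[str, int] = field(default_factory=dict)
    n_targets: int = 300
    named_targets: tuple[str, ...] = ()
    ghost_only_target: str | None = None
    seed: int = 0


def generate_network(
    config: NetworkConfig,
) -> tuple[BipartiteNetwork, DetectionEvidence]:
    """Build a bipartite network realizing the requested degree profile.

    Named ghost compounds receive exactly their requested distinct-target
    degrees; evidenced compounds receive theirs but never touch the reserved
    ghost-only target, so that target (when requested) enters the network
    solely through ghosts.
    """
    rng = np.random.default_rng(config.seed)
    named = list(dict.fromkeys(config.named_targets))
    if config.ghost_only_target and config.ghost_only_target not in named:
        named.insert(0, config.ghost_only_target)
    fillers = [f"T{i:04d}" for i in range(1, config.n_targets - len(named) + 1)]
    targets = named + fillers
    if len(targets) < len(named):
        raise ValueError("n_targets smaller than the named target list")
    open_targets = [t for t in targets if t != config.ghost_only_target]

    for name, deg in {**config.ghost_degrees, **config.evidenced_degrees}.items():
        cap = len(targets) if name in config.ghost_degrees else len(open_targets)
        if deg > cap:
            raise ValueError(f"infeasible degree {deg} for {name!r}: only "
                             f"{cap} eligible targets")
        if deg < 0:
            raise ValueError("degrees must be non-negative")

    edges: list[tuple[str, str, str]] = []
    first_ghost = True
    for compound, deg in config.ghost_degrees.items():
        pool = list(targets)
        chosen: list[str] = []
        if config.ghost_only_target and first_ghost and deg > 0:
            chosen.append(config.ghost_only_target)
            pool.remove(config.ghost_only_target)
            first_ghost = False
        extra = rng.choice(len(pool), size=deg - len(chosen), replace=False)
        chosen.extend(pool[j] for j in extra)
        edges.extend((compound, t, "predicted") for t in chosen)
    for compound, deg in config.evidenced_degrees.items():
        idx = rng.choice(len(open_targets), size=deg, replace=False)
        edges.extend((compound, open_targets[j], "predicted") for j in idx)

    compounds = frozenset(config.ghost_degrees) | frozenset(config.evidenced_degrees)
    covered = {t for _c, t, _s in edges}
    net = BipartiteNetwork(compounds, frozenset(covered), tuple(edges))
    evidence = DetectionEvidence(frozenset(config.evidenced_degrees))
    return net, evidence


# --------------------------------------------------------------------------
# pinned fixtures reproducing the printed census arithmetic
# --------------------------------------------------------------------------

_EXCL_T1 = {
    Category.METABOLITE: {
        ExclusionReason.SINGLE_COMPOUND_STUDY: 305,
        ExclusionReason.NO_MATCHING_HEADING: 259,
        ExclusionReason.EXCEEDS_THRESHOLD: 8,
        ExclusionReason.INCOMPLETE_DATA: 1,
    },
    Category.TARGET: {
        ExclusionReason.NO_MATCHING_HEADING: 107,
        ExclusionReason.EXCEEDS_THRESHOLD: 49,
        ExclusionReason.INCOMPLETE_DATA: 2,
    },
    Category.PATHWAY: {
        ExclusionReason.NO_MATCHING_HEADING: 87,
        ExclusionReason.EXCEEDS_THRESHOLD: 30,
        ExclusionReason.INCOMPLETE_DATA: 4,
    },
}

_HEADINGS = {
    Category.METABOLITE: "key metabolites",
    Category.TARGET: "core targets",
    Category.PATHWAY: "key pathways",
}


class _Builder:
    """Assembles pinned records: per-study flags and per-category lists."""

    def __init__(self, rng: np.random.Generator, n: int = _N_REF):
        self.rng = rng
        self.ids = [f"S{i + 1:05d}" for i in range(n)]
        self.focus = {aid: StudyFocus.MIXTURE for aid in self.ids}
        self.mmeth = {aid: MetaboliteMethod.DATABASE_ONLY for aid in self.ids}
        self.tmeth = {aid: TargetMethod.DATABASE_ONLY for aid in self.ids}
        self.complete = {aid: {c: True for c in CATEGORIES} for aid in self.ids}
        self.lists = {aid: [] for aid in self.ids}

    def partition(self, excl: Mapping[ExclusionReason, int]) -> dict:
        """Shuffle ids and slice off one block per exclusion reason; the
        remainder is the included cohort."""
        perm = list(self.rng.permutation(self.ids))
        parts: dict = {}
        pos = 0
        for reason in _ROLE_ORDER:
            c = int(excl.get(reason, 0))
            parts[reason] = perm[pos:pos + c]
            pos += c
        parts["included"] = perm[pos:]
        return parts

    def assign(self, pool: Sequence[str], count: int) -> set[str]:
        idx = self.rng.choice(len(pool), size=count, replace=False)
        return {pool[i] for i in idx}

    def populate(
        self,
        category: Category,
        parts: Mapping,
        members: Mapping[str, set[str]],
        min_len: Mapping[str, int] | None = None,
    ) -> None:
        """Attach finding lists: pinned element memberships for included
        studies (padded with unique fillers), plus the designated exclusion
        shapes for the excluded blocks."""
        heading = _HEADINGS[category]
        order = list(members)
        min_len = min_len or {}
        for aid in parts["included"]:
            items = [el for el in order if aid in members[el]]
            need = max(min_len.get(aid, 1), 1)
            j = 0
            while len(items) < need:
                j += 1
                items.append(f"filler-{category.value[0]}-{aid}-{j}")
            self.lists[aid].append(FindingList(category, heading, tuple(items)))
        for aid in parts[ExclusionReason.SINGLE_COMPOUND_STUDY]:
            self.focus[aid] = StudyFocus.SINGLE_COMPOUND
            self.lists[aid].append(
                FindingList(category, heading, ("Paeoniflorin",)))
        for aid in parts[ExclusionReason.INCOMPLETE_DATA]:
            self.complete[aid][category] = False
            self.lists[aid].append(
                FindingList(category, heading, (f"filler-{aid}-inc",)))
        for aid in parts[ExclusionReason.NO_MATCHING_HEADING]:
            self.lists[aid].append(FindingList(
                category, DECOY_HEADINGS[0],
                (f"filler-{aid}-nh1", f"filler-{aid}-nh2")))
        for aid in parts[ExclusionReason.EXCEEDS_THRESHOLD]:
            items = tuple(f"bulk-{category.value[0]}-{aid}-{j}"
                          for j in range(31))
            self.lists[aid].append(FindingList(category, heading, items))

    def build(self) -> Corpus:
        records = tuple(
            ArticleRecord(
                article_id=aid, study_focus=self.focus[aid],
                metabolite_method=self.mmeth[aid],
                target_method=self.tmeth[aid],
                complete=self.complete[aid],
                finding_lists=tuple(self.lists[aid]),
            )
            for aid in self.ids
        )
        return Corpus(records, Provenance(source="synthetic", timestamp=""))


def table1_fixture(seed: int = 0) -> Corpus:
    """1,038-study corpus pinned to the headline census arithmetic: cohorts
    465/880/917 and the printed top-3 n/N pairs per category."""
    b = _Builder(np.random.default_rng((seed, 1)))
    pins = {
        Category.METABOLITE: {"Quercetin": 294, "Kaempferol": 223,
                              "Luteolin": 144},
        Category.TARGET: {"AKT1": 429, "TNF": 344, "EGFR": 306},
        Category.PATHWAY: {"AGE-RAGE signaling pathway": 504,
                           "PI3K-Akt signaling pathway": 502,
                           "Lipid and atherosclerosis": 460},
    }
    for category in CATEGORIES:
        parts = b.partition(_EXCL_T1[category])
        incl = parts["included"]
        members = {el: b.assign(incl, n) for el, n in pins[category].items()}
        b.populate(category, parts, members)
    return b.build()


def top5_fixture(seed: int = 0) -> Corpus:
    """Corpus pinned to the strict-threshold sensitivity arithmetic: 258 of
    the 465 metabolite-cohort studies report ≤5 metabolites, 162 of them
    listing the top metabolite (62.8%); 93/261 for the top target (35.6%)."""
    b = _Builder(np.random.default_rng((seed, 2)))
    layout = {
        Category.METABOLITE: ("Quercetin", 258, 162, 132),
        Category.TARGET: ("AKT1", 261, 93, 336),
    }
    for category in CATEGORIES:
        parts = b.partition(_EXCL_T1[category])
        incl = parts["included"]
        if category in layout:
            element, n_short, n_el_short, n_el_long = layout[category]
            short = sorted(b.assign(incl, n_short))
            long = [aid for aid in incl if aid not in set(short)]
            members = {element: b.assign(short, n_el_short)
                       | b.assign(long, n_el_long)}
            min_len = {aid: 6 for aid in long}  # long lists exceed the Top-5 cut
            b.populate(category, parts, members, min_len=min_len)
        else:
            b.populate(category, parts, {})
    return b.build()


def table2_fixture(seed: int = 0) -> Corpus:
    """Corpus pinned to the stratified contrast: database-dependent vs.
    experiment/omics-integrated prevalence of the top elements."""
    b = _Builder(np.random.default_rng((seed, 3)))
    strata_pins = {
        Category.METABOLITE: (
            328, 137, 0,
            {"Quercetin": (236, 58), "Kaempferol": (178, 45),
             "Beta-sitosterol": (120, 0), "Luteolin": (115, 29),
             "Stigmasterol": (57, 0), "Naringenin": (0, 20),
             "Isorhamnetin": (0, 20)},
        ),
        Category.TARGET: (
            725, 153, 2,
            {"AKT1": (398, 30), "TNF": (309, 35), "EGFR": (270, 36),
             "IL6": (256, 37), "ESR1": (235, 33), "PTGS2": (0, 37)},
        ),
    }
    for category in CATEGORIES:
        parts = b.partition(_EXCL_T1[category])
        incl = parts["included"]
        if category in strata_pins:
            n_db, n_int, n_unknown, pins = strata_pins[category]
            assert n_db + n_int + n_unknown == len(incl)
            perm = list(b.rng.permutation(incl))
            db_ids = perm[:n_db]
            int_ids = perm[n_db:n_db + n_int]
            unk_ids = perm[n_db + n_int:]
            # database_only is the builder default for db_ids
            for aid in int_ids:
                if category == Category.METABOLITE:
                    b.mmeth[aid] = MetaboliteMethod.EXPERIMENTAL_INTEGRATED
                else:
                    b.tmeth[aid] = TargetMethod.OMICS_INTEGRATED
            for aid in unk_ids:
                if category == Category.METABOLITE:
                    b.mmeth[aid] = MetaboliteMethod.UNKNOWN
                else:
                    b.tmeth[aid] = TargetMethod.UNKNOWN
            members = {
                el: b.assign(db_ids, c_db) | b.assign(int_ids, c_int)
                for el, (c_db, c_int) in pins.items()
            }
            b.populate(category, parts, members)
        else:
            b.populate(category, parts, {})
    return b.build()


@dataclass(frozen=True)
class TaohongFixture:
    network: BipartiteNetwork
    evidence: DetectionEvidence
    prioritized_ghosts: tuple[str, ...]
    core_reference: frozenset[str]
    core_database: frozenset[str]


def taohong_fixture(seed: int = 0) -> TaohongFixture:
    """Synthetic stand-in for the Taohong Siwu Decoction re-analysis.

    Embeds the printed ghost degree profile (223, 125, 119, 118, 109), a
    reserved hub target reachable only through ghosts, in-vivo-evidenced
    phenolic constituents with modest degrees, and the two printed
    core-target sets.  The full edge lists of the original analysis are not
    public; everything beyond the pinned values is synthetic.
    """
    rng = np.random.default_rng((seed, 4))
    ghost_degrees = {
        "Quercetin": 223, "Luteolin": 125, "Kaempferol": 119,
        "Baicalein": 118, "Beta-sitosterol": 109, "Beta-carotene": 41,
    }
    evidenced = {
        "Ferulic acid": 38, "Vanillic acid": 29, "Hydroxysafflor yellow A": 36,
        "Amygdalin": 24, "Paeoniflorin": 35, "Gallic acid": 27,
        "Albiflorin": 31, "Oleic acid": 33,
    }
    named_targets = ("AKT1", "TP53", "HSP90AA1", "JUN", "EP300", "PTGS2",
                     "BCL2", "ESR1", "PPARG")
    net, evidence = generate_network(NetworkConfig(
        ghost_degrees=ghost_degrees,
        evidenced_degrees=evidenced,
        n_targets=300,
        named_targets=named_targets,
        ghost_only_target="AKT1",
        seed=int(rng.integers(2 ** 31)),
    ))
    return TaohongFixture(
        network=net,
        evidence=evidence,
        prioritized_ghosts=("Quercetin", "Luteolin", "Kaempferol",
                            "Baicalein", "Beta-sitosterol"),
        core_reference=frozenset({"JUN", "PTGS2", "BCL2", "ESR1", "PPARG"}),
        core_database=frozenset({"TP53", "HSP90AA1", "AKT1", "JUN", "EP300"}),
    )


FIXTURES = {
    "table1": table1_fixture,
    "table2": table2_fixture,
    "top5": top5_fixture,
}
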