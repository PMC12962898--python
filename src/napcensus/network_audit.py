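"""Compound–target network audit: degree bias and "chemical ghosts".

A compound–target network predicted from phytochemical databases can contain
*chemical ghosts* — compounds with no evidence of in-vivo exposure (absent
from the preparation's measured plasma/blood constituents) that nonetheless
carry very large predicted target degrees.  A *ghost-only target* enters the
network exclusively through ghost compounds: remove the ghosts and the
target's entire mechanistic rationale disappears.

This module loads a user-supplied edge list (it never queries prediction
databases), canonicalizes node names through the synonym map, and computes
the audit statistics: per-compound distinct-target degrees, subset and
background mean degrees, the ghost and ghost-only-target sets, and a
comparison between two candidate core-target sets (intersection, Jaccard
index, asymmetric differences).
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx

from .census import round_half_up
from .corpus import SchemaError, SynonymMap

_COMPOUND = 0
_TARGET = 1


@dataclass(frozen=True)
class BipartiteNetwork:
    """Deduplicated bipartite compound–target network.

    ``edges`` holds canonicalized ``(compound, target, source_label)``
    triples; duplicate (compound, target) pairs collapse, keeping the first
    source label.  Compounds and targets live in separate namespaces, so a
    name may legally appear on both sides.
    """

    compounds: frozenset[str]
    targets: frozenset[str]
    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))
        object.__setattr__(self, "targets", frozenset(self.targets))
        seen: set[tuple[str, str]] = set()
        dedup = []
        for compound, target, *rest in self.edges:
            if compound not in self.compounds:
                raise ValueError(f"edge references undeclared compound {compound!r}")
            if target not in self.targets:
                raise ValueError(f"edge references undeclared target {target!r}")
            if (compound, target) in seen:
                continue
            seen.add((compound, target))
            dedup.append((compound, target, rest[0] if rest else ""))
        object.__setattr__(self, "edges", tuple(dedup))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        """networkx view (nodes tagged with ``kind``/``bipartite``)."""
        g = nx.Graph()
        g.add_nodes_from(((("c", c) for c in self.compounds)), bipartite=_COMPOUND)
        g.add_nodes_from(((("t", t) for t in self.targets)), bipartite=_TARGET)
        g.add_edges_from(
            (("c", c), ("t", t), {"source": s}) for c, t, s in self.edges
        )
        return g

    def targets_of(self, compound: str) -> frozenset[str]:
        return frozenset(t for c, t, _ in self.edges if c == compound)

    def compounds_of(self, target: str) -> frozenset[str]:
        return frozenset(c for c, t, _ in self.edges if t == target)


@dataclass(frozen=True)
class DetectionEvidence:
    """Compounds with in-vivo detection support (e.g. blood-absorbed
    constituents).  May list compounds absent from a given network."""

    compounds: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))

    def __contains__(self, compound: str) -> bool:
        return compound in self.compounds


def canonicalize_evidence(
    names: Iterable[str], synonyms: SynonymMap
) -> DetectionEvidence:
    return DetectionEvidence(frozenset(synonyms.apply(n) for n in names))


def load_edges(path: str | Path, synonyms: SynonymMap) -> BipartiteNetwork:
    """Load a delimited edge list (``compound<TAB>target[<TAB>source]``).

    Tab- and comma-delimited files are both accepted (sniffed from the
    header); names are canonicalized through the synonym map and duplicate
    pairs collapse.  Malformed rows raise a row-numbered :class:`SchemaError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    errors: list[str] = []
    compounds: set[str] = set()
    targets: set[str] = set()
    edges: list[tuple[str, str, str]] = []
    reader = csv.reader(text.splitlines(), delimiter=delimiter)
    header = next(reader, None)
    if header is None or [h.strip().lower() for h in header[:2]] != ["compound", "target"]:
        raise SchemaError([f"{path.name}: expected header starting "
                           f"'compound{delimiter}target', got {header!r}"])
    for lineno, row in enumerate(reader, start=2):
        if len(row) not in (2, 3) or not row[0].strip() or not row[1].strip():
            errors.append(f"{path.name} row {lineno}: malformed edge row {row!r}")
            continue
        compound = synonyms.apply(row[0])
        target = synonyms.apply(row[1])
        source = row[2].strip() if len(row) == 3 else ""
        compounds.add(compound)
        targets.add(target)
        edges.append((compound, target, source))
    if errors:
        raise SchemaError(errors)
    return BipartiteNetwork(frozenset(compounds), frozenset(targets), tuple(edges))


def load_evidence(path: str | Path, synonyms: SynonymMap) -> DetectionEvidence:
    """Load an evidence file: one compound name per line, '#' comments."""
    names = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return canonicalize_evidence(names, synonyms)


# --------------------------------------------------------------------------
# audit statistics
# --------------------------------------------------------------------------


def compound_degrees(net: BipartiteNetwork) -> dict[str, int]:
    """Distinct-target count per compound; isolated declared compounds
    report 0."""
    degrees = {c: 0 for c in net.compounds}
    for compound, _target, _src in net.edges:
        degrees[compound] += 1  # edges are deduplicated pairs
    return degrees


class MeanDegree(NamedTuple):
    mean: float
    rounded: int


def mean_degree(net: BipartiteNetwork, subset: Iterable[str]) -> MeanDegree:
    """Arithmetic mean of the subset's degrees, with its half-up integer
    rounding (degrees 223,125,119,118,109 → 138.8 → 139)."""
    subset = list(subset)
    if not subset:
        raise ValueError("mean_degree over an empty compound subset")
    degrees = compound_degrees(net)
    missing = [c for c in subset if c not in degrees]
    if missing:
        raise KeyError(f"compounds not in network: {missing}")
    mean = sum(degrees[c] for c in subset) / len(subset)
    return MeanDegree(mean, int(round_half_up(mean, 0)))


def flag_ghosts(net: BipartiteNetwork, evidence: DetectionEvidence) -> frozenset[str]:
    """Network compounds lacking in-vivo detection evidence."""
    return net.compounds - evidence.compounds


def ghost_only_targets(
    net: BipartiteNetwork, evidence: DetectionEvidence
) -> frozenset[str]:
    """Targets with ≥1 edge whose incident compounds are all ghosts.

    Antitone in evidence: adding evidence can only shrink this set.
    """
    ghosts = flag_ghosts(net, evidence)
    incident: dict[str, list[str]] = {}
    for compound, target, _src in net.edges:
        incident.setdefault(target, []).append(compound)
    return frozenset(
        t for t, comps in incident.items() if all(c in ghosts for c in comps)
    )


@dataclass(frozen=True)
class CoreSetComparison:
    a_only: frozenset[str]
    b_only: frozenset[str]
    intersection: frozenset[str]
    jaccard: float


def compare_core_sets(a: Iterable[str], b: Iterable[str]) -> CoreSetComparison:
    """Intersection, Jaccard index and asymmetric differences of two core
    target sets.  Two empty sets are identical, hence Jaccard 1.0."""
    a, b = frozenset(a), frozenset(b)
    union = a | b
    inter = a & b
    jaccard = len(inter) / len(union) if union else 1.0
    return CoreSetComparison(a - b, b - a, inter, jaccard)


@dataclass(frozen=True)
class GhostAudit:
    """Full ghost audit of one network against one evidence set."""

    ghost_compounds: frozenset[str]
    degrees: Mapping[str, int]
    ghost_mean_degree: MeanDegree | None
    background_mean_degree: MeanDegree | None
    ghost_only_targets: frozenset[str]
    core_comparison: CoreSetComparison | None = None
    prioritized: tuple[str, ...] = ()


def audit_network(
    net: BipartiteNetwork,
    evidence: DetectionEvidence,
    core_a: Iterable[str] | None = None,
    core_b: Iterable[str] | None = None,
    prioritized: Sequence[str] | None = None,
) -> GhostAudit:
    """Run the complete audit.

    ``prioritized`` optionally names the ghost subset whose mean degree is
    reported (e.g. the top-degree ghosts a study foregrounded); it defaults
    to all flagged ghosts.  The background mean is taken over the evidenced
    (non-ghost) compounds.
    """
    ghosts = flag_ghosts(net, evidence)
    degrees = compound_degrees(net)
    subset = tuple(prioritized) if prioritized else tuple(sorted(ghosts))
    bad = [c for c in subset if c not in ghosts]
    if bad:
        raise ValueError(f"prioritized compounds are not ghosts: {bad}")
    ghost_mean = mean_degree(net, subset) if subset else None
    background = sorted(net.compounds - ghosts)
    background_mean = mean_degree(net, background) if background else None
    comparison = None
    if core_a is not None and core_b is not None:
        comparison = compare_core_sets(core_a, core_b)
    return GhostAudit(
        ghost_compounds=ghosts,
        degrees=degrees,
        ghost_mean_degree=ghost_mean,
        background_mean_degree=background_mean,
        ghost_only_targets=ghost_only_targets(net, evidence),
        core_comparison=comparison,
        prioritized=subset,
    )


def write_audit_report(audit: GhostAudit, out_dir: str | Path) -> dict:
    """Write ``audit_summary.json`` + ``audit_compounds.csv``; returns the
    summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "audit_compounds.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(("compound", "degree", "ghost"))
        for compound in sorted(audit.degrees):
            w.writerow((compound, audit.degrees[compound],
                        str(compound in audit.ghost_compounds).lower()))
    summary = {
        "n_compounds": len(audit.degrees),
        "n_ghosts": len(audit.ghost_compounds),
        "ghost_compounds": sorted(audit.ghost_compounds),
        "prioritized": list(audit.prioritized),
        "ghost_mean_degree": (
            None if audit.ghost_mean_degree is None
            else {"mean": audit.ghost_mean_degree.mean,
                  "rounded": audit.ghost_mean_degree.rounded}
        ),
        "background_mean_degree": (
            None if audit.background_mean_degree is None
            else {"mean": audit.background_mean_degree.mean,
                  "rounded": audit.background_mean_degree.rounded}
        ),
        "ghost_only_targets": sorted(audit.ghost_only_targets),
        "core_comparison": (
            None if audit.core_comparison is None
            else {
                "intersection": sorted(audit.core_comparison.intersection),
                "jaccard": audit.core_comparison.jaccard,
                "a_only": sorted(audit.core_comparison.a_only),
                "b_only": sorted(audit.core_comparison.b_only),
            }
        ),
    }
    (out_dir / "audit_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
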