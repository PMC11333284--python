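"""Phenotype ontology handling: is-a DAGs, ancestral closures and information content.

Patient phenotypes are coded with terms from a directed acyclic ontology of
``is_a`` relations (HPO-style).  Everything downstream — Resnik similarity,
phenotypic homogeneity, term enrichment — rests on three primitives defined
here: the ancestral closure ``anc(t)`` of a term (the term together with every
term reachable via parent edges), the annotation closure of a participant's
term set, and the information content ``IC(t) = -log f(t)`` where ``f(t)`` is
the fraction of participants in a reference cohort whose *closed* annotation
set contains ``t``.  Closing annotations before computing frequencies makes
``f`` monotone nonincreasing from ancestor to descendant, which in turn makes
Resnik similarity well behaved.

Natural logarithms are used throughout, so IC is measured in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import obonet

__all__ = [
    "OntologyGraph",
    "AnnotationSet",
    "ICTable",
    "load_obo",
    "ancestors",
    "close_annotations",
    "ic_table",
    "minimal_terms",
]


class OntologyError(ValueError):
    """Structural problem with an ontology (cycle, missing root, unknown term)."""


@dataclass
class OntologyGraph:
    """An is-a DAG of phenotype terms.

    ``parents`` maps each term to its set of is-a parents; the unique ``root``
    has none.  Only is-a edges are represented: other OBO relationship types
    (part_of etc.) are ignored at load time.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    root: str
    names: dict[str, str] = field(default_factory=dict)
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise OntologyError(f"parent {p!r} of {child!r} is not a term")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("is-a graph contains a cycle")
        roots = {t for t in self.terms if not self.parents.get(t)}
        if not roots:
            raise OntologyError("ontology has no root term")
        if roots != {self.root}:
            raise OntologyError(
                f"expected single root {self.root!r}, found parentless terms {sorted(roots)}"
            )
        # every term must reach the root
        for t in self.terms:
            if self.root not in self.ancestors(t):
                raise OntologyError(f"term {t!r} does not reach root {self.root!r}")

    def ancestors(self, t: str) -> frozenset[str]:
        """``anc(t)``: the union of ``t`` and all its ancestral terms."""
        if t not in self.terms:
            raise KeyError(f"unknown term {t!r}")
        cached = self._anc_cache.get(t)
        if cached is not None:
            return cached
        out: set[str] = {t}
        for p in self.parents.get(t, ()):
            out |= self.ancestors(p)
        result = frozenset(out)
        self._anc_cache[t] = result
        return result


@dataclass(frozen=True)
class AnnotationSet:
    """One participant's phenotype term set."""

    participant: str
    terms: frozenset[str]


@dataclass
class ICTable:
    """Per-term annotation frequency and information content (nats).

    Terms absent from every closed annotation set have frequency 0 and carry an
    ``inf`` IC sentinel; similarity code must skip them when maximizing over
    common ancestors.
    """

    frequency: dict[str, float]
    ic: dict[str, float]

    def finite_ic(self, t: str) -> float | None:
        v = self.ic.get(t)
        if v is None or math.isinf(v):
            return None
        return v


def load_obo(path) -> OntologyGraph:
    """Load an OBO file, honoring only is-a edges and dropping obsolete terms."""
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    terms = set(multigraph.nodes)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    g = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    g.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError(f"cycle among is-a relations in {path}")
    roots = sorted(t for t in terms if not parents[t])
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root term in {path}, found {roots}")
    names = {t: data.get("name", t) for t, data in multigraph.nodes(data=True)}
    return OntologyGraph(terms=terms, parents=parents, root=roots[0], names=names)


def ancestors(graph: OntologyGraph, t: str) -> frozenset[str]:
    return graph.ancestors(t)


def close_annotations(
    graph: OntologyGraph, annots: list[AnnotationSet]
) -> list[AnnotationSet]:
    """Replace each term set by the union of the ancestral closures of its terms.

    Idempotent; the root joins every nonempty set.
    """
    out = []
    for a in annots:
        closed: set[str] = set()
        for t in a.terms:
            closed |= graph.ancestors(t)
        out.append(AnnotationSet(participant=a.participant, terms=frozenset(closed)))
    return out


def ic_table(graph: OntologyGraph, closed_annots: list[AnnotationSet]) -> ICTable:
    """Term frequencies over a closed reference cohort and IC = -ln(frequency)."""
    n = len(closed_annots)
    if n == 0:
        raise ValueError("cannot compute term frequencies over an empty cohort")
    counts: dict[str, int] = {t: 0 for t in graph.terms}
    for a in closed_annots:
        for t in a.terms:
            if t not in counts:
                raise KeyError(f"annotation term {t!r} not in ontology")
            counts[t] += 1
    frequency = {t: c / n for t, c in counts.items()}
    ic = {
        t: (-math.log(f) if f > 0 else math.inf) for t, f in frequency.items()
    }
    return ICTable(frequency=frequency, ic=ic)


def minimal_terms(graph: OntologyGraph, terms: set[str]) -> set[str]:
    """Drop every member that is a strict ancestor of another member."""
    terms = set(terms)
    strict_ancestors: set[str] = set()
    for t in terms:
        strict_ancestors |= graph.ancestors(t) - {t}
    return {t for t in terms if t not in strict_ancestors}
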