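"""Solved-case depletion, HPO term enrichment and etiological prevalence ranking.

Three complementary summaries of a candidate case group:

* a one-sided binomial test for depletion of diagnostically solved cases
  relative to the cohort's baseline solve rate (a group explained by a new
  etiology should contain fewer solved cases than chance predicts);
* Fisher two-sided exact tests for over/under-representation of HPO terms in
  the case group versus a background cohort, restricted to terms carried by a
  minimum number of cases and nonredundant within each frequency level, with
  Bonferroni adjustment by multiplication;
* a prevalence ranking of etiological genes by the number of cases they
  explain out of a phenotype-coded denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy.stats import binom, fisher_exact

from .ontology import AnnotationSet, OntologyGraph, minimal_terms

__all__ = [
    "EnrichmentRow",
    "PrevalenceRow",
    "depletion_binomial_test",
    "select_testable_terms",
    "term_enrichment",
    "prevalence_table",
    "summary_term_graph",
]


@dataclass
class EnrichmentRow:
    term: str
    n_cases_with: int
    n_cases: int
    n_background_with: int
    n_background: int
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class PrevalenceRow:
    gene: str
    n_cases: int
    denominator: int
    percent: float


def depletion_binomial_test(
    n_group: int, n_unexplained_in_group: int, baseline_solved_rate: float
) -> float:
    """One-sided P for observing so few solved cases in the group.

    With X ~ Binomial(n_group, baseline_solved_rate) counting solved cases,
    returns P(X <= n_group - n_unexplained_in_group).
    """
    if not 0 <= n_unexplained_in_group <= n_group:
        raise ValueError("require 0 <= n_unexplained <= n_group")
    if not 0.0 <= baseline_solved_rate <= 1.0:
        raise ValueError("baseline solve rate must be in [0, 1]")
    n_solved = n_group - n_unexplained_in_group
    return float(binom.cdf(n_solved, n_group, baseline_solved_rate))


def _case_counts(case_annotations: list[AnnotationSet]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in case_annotations:
        for t in a.terms:
            counts[t] = counts.get(t, 0) + 1
    return counts


def select_testable_terms(
    graph: OntologyGraph,
    case_annotations: list[AnnotationSet],
    min_count: int = 5,
) -> set[str]:
    """Terms carried by >= min_count cases, nonredundant per frequency level.

    Within each distinct case-count value, terms that are strict ancestors of
    another term with the same count are dropped (the ancestor is implied by
    closure and adds no information); terms at different counts are kept even
    when related.
    """
    counts = _case_counts(case_annotations)
    eligible = {t for t, c in counts.items() if c >= min_count}
    keep: set[str] = set()
    by_count: dict[int, set[str]] = {}
    for t in eligible:
        by_count.setdefault(counts[t], set()).add(t)
    for level_terms in by_count.values():
        keep |= minimal_terms(graph, level_terms)
    return keep


def term_enrichment(
    graph: OntologyGraph,
    case_annots: list[AnnotationSet],
    background_annots: list[AnnotationSet],
    min_count: int = 5,
) -> list[EnrichmentRow]:
    """Fisher two-sided exact tests over the testable terms.

    The two-sided P sums all tables with fixed margins whose point probability
    does not exceed the observed table's.  Bonferroni adjustment multiplies by
    the number of testable terms, capped at 1; adjusted P < 0.05 is flagged
    significant.  Rows are sorted by adjusted then raw P.
    """
    if not background_annots:
        raise ValueError("background cohort is empty")
    case_ids = {a.participant for a in case_annots}
    bg_ids = {a.participant for a in background_annots}
    if case_ids & bg_ids:
        raise ValueError("case and background participant sets must be disjoint")
    testable = select_testable_terms(graph, case_annots, min_count)
    n_tests = len(testable)
    n_cases = len(case_annots)
    n_bg = len(background_annots)
    case_counts = _case_counts(case_annots)
    bg_counts = _case_counts(background_annots)
    rows = []
    for t in sorted(testable):
        a = case_counts.get(t, 0)
        c = bg_counts.get(t, 0)
        table = [[a, n_cases - a], [c, n_bg - c]]
        p_raw = float(fisher_exact(table, alternative="two-sided")[1])
        p_adj = min(1.0, p_raw * n_tests)
        rows.append(
            EnrichmentRow(
                term=t,
                n_cases_with=a,
                n_cases=n_cases,
                n_background_with=c,
                n_background=n_bg,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < 0.05,
            )
        )
    rows.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return rows


def prevalence_table(
    solved_counts: dict[str, int],
    special_counts: dict[str, int] | None = None,
    denominator: int = 0,
    min_count: int = 11,
) -> list[PrevalenceRow]:
    """Rank etiological genes by cases explained per phenotype-coded case.

    ``special_counts`` overrides entries of ``solved_counts`` (used for genes
    whose case count comes from a variant-region definition rather than the
    diagnostic pipeline).  Genes below ``min_count`` are dropped; ranking is by
    count descending with gene-name tie-break; percentages are rendered to two
    decimals.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    merged = dict(solved_counts)
    merged.update(special_counts or {})
    rows = [
        PrevalenceRow(
            gene=g,
            n_cases=c,
            denominator=denominator,
            percent=round(100.0 * c / denominator, 2),
        )
        for g, c in merged.items()
        if c >= min_count
    ]
    rows.sort(key=lambda r: (-r.n_cases, r.gene))
    return rows


def summary_term_graph(
    graph: OntologyGraph,
    case_annots: list[AnnotationSet],
    enrichment: list[EnrichmentRow],
    majority_fraction: float = 0.5,
) -> nx.DiGraph:
    """DAG of majority and significantly enriched terms with connecting ancestors.

    Selected terms are those present in at least ``majority_fraction`` of
    cases or significantly enriched, reduced to a nonredundant set per
    frequency level.  Their ancestor closure is added, edges are the
    transitive reduction of is-a, and non-selected pass-through ancestors
    (single child, not the root) are contracted away so only branching
    connectors remain.  Nodes carry case counts, percentages and significance.
    """
    if not case_annots:
        raise ValueError("case set is empty")
    n_cases = len(case_annots)
    counts = _case_counts(case_annots)
    significant = {r.term for r in enrichment if r.significant}
    majority = {
        t for t, c in counts.items() if c / n_cases >= majority_fraction
    }
    selected = majority | significant
    by_count: dict[int, set[str]] = {}
    for t in selected:
        by_count.setdefault(counts.get(t, 0), set()).add(t)
    kept: set[str] = set()
    for level_terms in by_count.values():
        kept |= minimal_terms(graph, level_terms)

    nodes: set[str] = set()
    for t in kept:
        nodes |= graph.ancestors(t)
    g = nx.DiGraph()
    for t in nodes:
        g.add_node(t)
        for p in graph.parents.get(t, ()):
            if p in nodes:
                g.add_edge(p, t)  # parent -> child for display
    g = nx.transitive_reduction(g)

    changed = True
    while changed:
        changed = False
        for t in list(g.nodes):
            if t in kept or t == graph.root:
                continue
            children = list(g.successors(t))
            if len(children) == 1:
                for p in g.predecessors(t):
                    g.add_edge(p, children[0])
                g.remove_node(t)
                changed = True

    for t in g.nodes:
        c = counts.get(t, 0)
        g.nodes[t]["label"] = graph.names.get(t, t)
        g.nodes[t]["n_cases"] = c
        g.nodes[t]["percent"] = round(100.0 * c / n_cases, 1)
        g.nodes[t]["significant"] = t in significant
        g.nodes[t]["selected"] = t in kept
    return g


def write_dot(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph terms {\n  rankdir=TB;\n")
        for t in sorted(g.nodes):
            d = g.nodes[t]
            label = f"{d.get('label', t)}\\n{d.get('n_cases', 0)} ({d.get('percent', 0)}%)"
            color = "red" if d.get("significant") else "black"
            fh.write(f'  "{t}" [label="{label}", color={color}];\n')
        for a, b in sorted(g.edges):
            fh.write(f'  "{a}" -> "{b}";\n')
        fh.write("}\n")


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def enrichment_to_rows(rows: list[EnrichmentRow]) -> list[dict]:
    return [vars(r) for r in rows]
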