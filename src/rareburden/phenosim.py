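"""Semantic phenotype similarity and the phenotypic homogeneity permutation test.

Term-level similarity is Resnik's: ``s(t1, t2) = max IC(t) over common
ancestors t of t1 and t2``.  Set-level similarity is the symmetric best-match
average (BMA): each term of one set is matched to its most similar term in the
other set and the two directional averages are themselves averaged.  The
phenotypic homogeneity of a group of k participants is the mean BMA over all
k-choose-2 unordered pairs.  Whether a group (say, carriers of a candidate
pathogenic variant) is more homogeneous than expected is assessed by a Monte
Carlo permutation test: random k-subsets of a reference population are scored
and the P value is the proportion of random subsets whose homogeneity is
greater than or equal to the observed one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .ontology import AnnotationSet, ICTable, OntologyGraph

__all__ = [
    "HomogeneityResult",
    "resnik",
    "bma",
    "homogeneity",
    "mc_homogeneity_test",
    "SimilarityIndex",
]


@dataclass
class HomogeneityResult:
    observed_h: float
    null_draws: int
    n_geq: int
    p_value: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def resnik(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor of t1 and t2.

    Zero-frequency terms (infinite IC sentinel) are excluded from the maximum.
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        raise ValueError(f"terms {t1!r} and {t2!r} share no ancestor")
    best = -math.inf
    for t in common:
        v = ic.ic.get(t)
        if v is not None and not math.isinf(v) and v > best:
            best = v
    if best == -math.inf:
        # all common ancestors unseen in the reference cohort; with closed
        # annotations the root always has frequency 1, so this indicates an
        # IC table computed on a foreign ontology
        raise ValueError(f"no common ancestor of {t1!r}, {t2!r} has finite IC")
    return best


class SimilarityIndex:
    """Caching engine for Resnik/BMA over a fixed ontology and IC table.

    Terms are interned to integer codes and a dense term-by-term Resnik matrix
    is filled lazily, so scoring many participant pairs (as the Monte Carlo
    test does) costs a few vectorized reductions per pair.
    """

    def __init__(self, graph: OntologyGraph, ic: ICTable):
        self.graph = graph
        self.ic = ic
        self._code: dict[str, int] = {}
        self._terms: list[str] = []
        self._matrix = np.zeros((0, 0))

    def _intern(self, terms) -> np.ndarray:
        new = [t for t in terms if t not in self._code]
        if new:
            old_n = len(self._terms)
            for t in new:
                self._code[t] = len(self._terms)
                self._terms.append(t)
            n = len(self._terms)
            m = np.full((n, n), np.nan)
            m[:old_n, :old_n] = self._matrix
            self._matrix = m
        return np.fromiter((self._code[t] for t in terms), dtype=np.intp)

    def _pair(self, i: int, j: int) -> float:
        v = self._matrix[i, j]
        if np.isnan(v):
            v = resnik(self.graph, self.ic, self._terms[i], self._terms[j])
            self._matrix[i, j] = self._matrix[j, i] = v
        return v

    def sim_submatrix(self, codes1: np.ndarray, codes2: np.ndarray) -> np.ndarray:
        sub = self._matrix[np.ix_(codes1, codes2)]
        if np.isnan(sub).any():
            for i in codes1:
                for j in codes2:
                    self._pair(int(i), int(j))
            sub = self._matrix[np.ix_(codes1, codes2)]
        return sub

    def bma(self, phi1, phi2) -> float:
        if not phi1 or not phi2:
            raise ValueError("best-match-average of an empty term set is undefined")
        c1 = self._intern(sorted(phi1))
        c2 = self._intern(sorted(phi2))
        sub = self.sim_submatrix(c1, c2)
        return 0.5 * sub.max(axis=1).mean() + 0.5 * sub.max(axis=0).mean()

    def pairwise(self, profiles: list[frozenset[str]]) -> np.ndarray:
        """Full symmetric BMA matrix over a list of term sets."""
        n = len(profiles)
        codes = [self._intern(sorted(p)) for p in profiles]
        out = np.zeros((n, n))
        for i in range(n):
            sub_ii = self.sim_submatrix(codes[i], codes[i])
            out[i, i] = 0.5 * sub_ii.max(axis=1).mean() + 0.5 * sub_ii.max(axis=0).mean()
            for j in range(i + 1, n):
                sub = self.sim_submatrix(codes[i], codes[j])
                out[i, j] = out[j, i] = (
                    0.5 * sub.max(axis=1).mean() + 0.5 * sub.max(axis=0).mean()
                )
        return out


def bma(graph: OntologyGraph, ic: ICTable, phi1, phi2) -> float:
    """Symmetric best-match-average similarity between two term sets."""
    return SimilarityIndex(graph, ic).bma(phi1, phi2)


def homogeneity(graph: OntologyGraph, ic: ICTable, groups: list) -> float:
    """Mean pairwise BMA similarity over all unordered pairs of term sets."""
    k = len(groups)
    if k < 2:
        raise ValueError("homogeneity requires at least two participants")
    idx = SimilarityIndex(graph, ic)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += idx.bma(groups[i], groups[j])
    return total / (k * (k - 1) / 2)


def _profiles_of(sets) -> list[frozenset[str]]:
    out = []
    for s in sets:
        terms = s.terms if isinstance(s, AnnotationSet) else frozenset(s)
        if not terms:
            raise ValueError("participant with an empty annotation set in group/population")
        out.append(frozenset(terms))
    return out


def mc_homogeneity_test(
    graph: OntologyGraph,
    ic: ICTable,
    group,
    population,
    n_draws: int = 100_000,
    seed: int = 0,
    add_one_correction: bool = False,
    index: SimilarityIndex | None = None,
    population_matrix: np.ndarray | None = None,
) -> HomogeneityResult:
    """Monte Carlo test for excess phenotypic homogeneity.

    Draws ``n_draws`` simple random subsets of ``k = len(group)`` participants
    (without replacement within a draw) from ``population``, scores each with
    :func:`homogeneity`, and returns the proportion of draws with homogeneity
    greater than or equal to the observed value as the one-sided P value.
    ``add_one_correction`` switches to the (r+1)/(n+1) estimator; the default
    is the plain proportion, which can be exactly zero.

    ``index`` and ``population_matrix`` (a precomputed pairwise BMA matrix over
    ``population``, as returned by :meth:`SimilarityIndex.pairwise`) allow the
    expensive similarity computations to be shared across repeated calls with
    the same population, e.g. in calibration experiments.
    """
    group_profiles = _profiles_of(group)
    pop_profiles = _profiles_of(population)
    k = len(group_profiles)
    if k < 2:
        raise ValueError("group must contain at least two participants")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    npop = len(pop_profiles)
    if npop < k:
        raise ValueError(f"population of size {npop} cannot yield subsets of size {k}")

    idx = index if index is not None else SimilarityIndex(graph, ic)

    # Pairwise BMA over population profiles once; each draw's homogeneity is a
    # mean over precomputed entries.
    if population_matrix is not None:
        if population_matrix.shape != (npop, npop):
            raise ValueError("population_matrix shape does not match population")
        pop_matrix = population_matrix
    else:
        pop_matrix = idx.pairwise(pop_profiles)
    iu, ju = np.triu_indices(k, 1)

    obs_matrix = idx.pairwise(group_profiles)
    observed_h = float(obs_matrix[np.triu_indices(k, 1)].mean())

    rng = np.random.default_rng(seed)
    n_geq = 0
    chunk = 2048
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        draws = np.empty((m, k), dtype=np.intp)
        for r in range(m):
            draws[r] = rng.choice(npop, size=k, replace=False)
        hs = pop_matrix[draws[:, iu], draws[:, ju]].mean(axis=1)
        n_geq += int((hs >= observed_h - 1e-12).sum())
        done += m

    if add_one_correction:
        p = (n_geq + 1) / (n_draws + 1)
    else:
        p = n_geq / n_draws
    return HomogeneityResult(
        observed_h=observed_h,
        null_draws=n_draws,
        n_geq=n_geq,
        p_value=p,
        seed=seed,
    )
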