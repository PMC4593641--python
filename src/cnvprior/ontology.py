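"""Taxonomy DAGs, annotation propagation and information-content similarity.

Both the gene-function ontology (GO-style) and the phenotype ontology
(HPO-style) are represented the same way: a directed acyclic graph of
terms connected by ``is a`` edges, plus a bipartite annotation graph
linking terms to targets (genes, or disorders).  Similarity between two
term sets is the classic Resnik-style construction: the information
content of the most informative common ancestor (MICA), averaged over
the first set after maximizing over the second::

    sim(X, Y) = avg_{x in X} max_{y in Y} IC(MICA(x, y))

with ``IC(t) = -ln(freq(t))`` where ``freq(t)`` is the fraction of
annotated targets carrying ``t`` after ancestor propagation.  Note the
measure is deliberately asymmetric (the average runs over ``X`` only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Taxonomy",
    "AnnotationGraph",
    "NO_INFORMATION",
    "propagate_annotations",
    "information_content",
    "mica",
    "set_similarity",
    "read_obo",
    "read_annotations",
]

#: Sentinel returned when a term (or term pair) carries no annotation
#: evidence at all, so no information content can be assigned.
NO_INFORMATION = None


class Taxonomy:
    """A DAG of terms with child -> parent ``is a`` edges.

    Parameters
    ----------
    terms
        Iterable of term identifiers.
    parent_edges
        Iterable of ``(child, parent)`` pairs.

    Raises
    ------
    ValueError
        If an edge references an unknown term or the graph is cyclic.
    """

    def __init__(self, terms: Iterable[str], parent_edges: Iterable[tuple[str, str]]):
        self._g = nx.DiGraph()
        self._g.add_nodes_from(terms)
        for child, parent in parent_edges:
            for t in (child, parent):
                if t not in self._g:
                    raise ValueError(f"edge references unknown term: {t!r}")
            self._g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValueError("taxonomy contains a directed cycle")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def parents(self, term: str) -> set[str]:
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._g.predecessors(term))

    def roots(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.out_degree(t) == 0}

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` *including itself* (reflexive closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            if term not in self._g:
                raise KeyError(f"unknown term: {term!r}")
            cached = frozenset(nx.descendants(self._g, term) | {term})
            self._ancestor_cache[term] = cached
        return cached

    def graph(self) -> nx.DiGraph:
        """The underlying child -> parent DiGraph (read-only use)."""
        return self._g


@dataclass
class AnnotationGraph:
    """Bipartite term <-> target mapping.

    ``term_targets`` maps a term to the set of targets it annotates;
    ``propagated`` records whether the ancestor closure has been applied.
    """

    term_targets: dict[str, set[str]] = field(default_factory=dict)
    propagated: bool = False

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationGraph":
        """Build from ``(term, target)`` pairs."""
        tt: dict[str, set[str]] = {}
        for term, target in pairs:
            tt.setdefault(term, set()).add(target)
        return cls(term_targets=tt)

    @property
    def targets(self) -> set[str]:
        out: set[str] = set()
        for s in self.term_targets.values():
            out |= s
        return out

    def targets_of(self, term: str) -> set[str]:
        return self.term_targets.get(term, set())

    def terms_of(self, target: str) -> set[str]:
        return {t for t, s in self.term_targets.items() if target in s}

    def edges(self) -> set[tuple[str, str]]:
        return {(t, n) for t, s in self.term_targets.items() for n in s}


def propagate_annotations(taxonomy: Taxonomy, raw: AnnotationGraph) -> AnnotationGraph:
    """Apply the ancestor closure: a target annotated with a term is
    considered annotated with every broader term as well.

    Idempotent; never removes edges.  Rejects terms absent from the
    taxonomy, naming the offender.
    """
    closed: dict[str, set[str]] = {}
    for term, targets in raw.term_targets.items():
        if term not in taxonomy:
            raise ValueError(f"annotation references unknown term: {term!r}")
        for anc in taxonomy.ancestors(term):
            closed.setdefault(anc, set()).update(targets)
    return AnnotationGraph(term_targets=closed, propagated=True)


def information_content(term: str, ag: AnnotationGraph) -> float | None:
    """``-ln`` of the fraction of targets annotated by ``term``.

    Returns :data:`NO_INFORMATION` when the term annotates no target
    (the frequency would be zero and the logarithm undefined).
    """
    if not ag.propagated:
        raise ValueError("annotation graph must be propagated before computing IC")
    n_term = len(ag.targets_of(term))
    if n_term == 0:
        return NO_INFORMATION
    return -math.log(n_term / len(ag.targets))


def mica(x: str, y: str, taxonomy: Taxonomy, ag: AnnotationGraph) -> str | None:
    """Most informative common ancestor of ``x`` and ``y``.

    A term is an ancestor of itself.  Candidates annotating zero targets
    are excluded.  Ties on IC are broken toward the lexicographically
    smallest identifier; no informative common ancestor (e.g. terms in
    different namespaces of a multi-rooted forest) yields
    :data:`NO_INFORMATION`.
    """
    common = taxonomy.ancestors(x) & taxonomy.ancestors(y)
    best: tuple[float, str] | None = None
    for cand in common:
        ic = information_content(cand, ag)
        if ic is NO_INFORMATION:
            continue
        key = (-ic, cand)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def set_similarity(
    X: Iterable[str],
    Y: Iterable[str],
    taxonomy: Taxonomy,
    ag: AnnotationGraph,
    symmetrize: bool = False,
) -> float:
    """Asymmetric IC similarity between two term sets.

    Average over ``x`` in ``X`` of the best ``IC(MICA(x, y))`` over ``y``
    in ``Y``.  Either set empty gives 0; a pair with no informative
    common ancestor contributes 0.  ``symmetrize=True`` averages the two
    directions (off by default; the asymmetric form is the definition).
    """
    X, Y = list(X), list(Y)
    if symmetrize:
        return 0.5 * (
            set_similarity(X, Y, taxonomy, ag)
            + set_similarity(Y, X, taxonomy, ag)
        )
    if not X or not Y:
        return 0.0
    total = 0.0
    for x in X:
        best = 0.0
        for y in Y:
            m = mica(x, y, taxonomy, ag)
            if m is NO_INFORMATION:
                continue
            best = max(best, information_content(m, ag))
        total += best
    return total / len(X)


# ---------------------------------------------------------------------------
# Readers

def read_obo(path: str) -> Taxonomy:
    """Read an OBO ontology, keeping only [Term] stanzas' id / is_a.

    Obsolete terms are dropped (obonet already excludes them); only
    ``is_a`` edges are retained — other relationship types play no role
    in the similarity measure.
    """
    import obonet

    g = obonet.read_obo(path)
    terms = set(g.nodes)
    edges = [
        (child, parent)
        for child, parent, key in g.edges(keys=True)
        if key == "is_a"
    ]
    return Taxonomy(terms, edges)


def read_annotations(path: str) -> tuple[AnnotationGraph, dict[tuple[str, str], str]]:
    """Read a tab-separated annotation file.

    Accepts either the minimal 2-column dialect ``target<TAB>term`` or a
    GAF-style 3-column dialect ``target<TAB>term<TAB>evidence_code``.
    Lines starting with ``!`` or ``#`` are comments.

    Returns the (unpropagated) annotation graph plus a map from
    ``(target, term)`` to evidence code (empty string when absent).
    """
    pairs: list[tuple[str, str]] = []
    evidence: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            target, term = fields[0], fields[1]
            code = fields[2] if len(fields) > 2 else ""
            pairs.append((term, target))
            evidence[(target, term)] = code
    return AnnotationGraph.from_pairs(pairs), evidence
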