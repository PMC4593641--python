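"""Gene feature vectors over a reduced (GO-Slim-style) function space.

Raw gene-function annotations are mapped to their nearest ancestors in a
slim cut of the ontology, filtered by evidence tier, and expanded with
the annotations of the gene's closest interaction-network neighbors.
Two weighting systems are supported:

* **network-uniform** — every slim term annotating the gene or a
  considered neighbor gets weight 1;
* **network-weighted** — each annotation contributes
  ``10**(-r) * 10**(-e)`` where ``r`` is the annotating member's
  random-walk rank (0 for the query gene itself) and ``e`` its evidence
  tier (1 experimental, 2 computational/inferred), summed over the query
  and its top-``k`` ranked neighbors.

The feature vector also carries a phenotype indicator block: one 0/1
column per phenotype term in the dataset vocabulary, set for the terms
of the patient whose CNV contains the gene.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .network import QuerySubnetwork
from .ontology import Taxonomy

__all__ = [
    "TIER1_CODES",
    "TIER2_CODES",
    "IGNORED_CODES",
    "evidence_tier",
    "SlimMap",
    "build_slim_map",
    "gene_go_profile",
    "GeneFeatureVector",
    "feature_weights_uniform",
    "feature_weights_network",
    "read_slim_terms",
]

# Standard partition of GO evidence codes into "experimentally proved"
# vs "computational / inferred" vs "no traceable source".
TIER1_CODES = {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
TIER2_CODES = {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "RCA", "IEA"}
IGNORED_CODES = {"ND", "NAS", "NR"}


def evidence_tier(code: str) -> int | None:
    """Tier of an evidence code: 1 experimental, 2 computational,
    ``None`` for no-source codes (annotation dropped).

    Unrecognized codes fall into tier 2 (treated as inferred evidence).
    """
    if code in TIER1_CODES:
        return 1
    if code in IGNORED_CODES:
        return None
    return 2


@dataclass
class SlimMap:
    """Mapping from every ontology term to its nearest slim ancestors."""

    slim_terms: frozenset[str]
    mapping: dict[str, frozenset[str]]

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.mapping.get(term, frozenset())


def build_slim_map(taxonomy: Taxonomy, slim_terms: set[str] | frozenset[str]) -> SlimMap:
    """Map each term to the slim term(s) at minimal is-a path length above it.

    A slim term maps to itself (distance 0).  When several slim terms
    tie at the minimal distance all are kept (map2slim-like semantics).
    Terms with no slim ancestor map to the empty set and contribute no
    feature.
    """
    slim = frozenset(slim_terms)
    unknown = slim - taxonomy.terms
    if unknown:
        raise ValueError(f"slim terms not in taxonomy: {sorted(unknown)}")
    mapping: dict[str, frozenset[str]] = {}
    for term in taxonomy.terms:
        # BFS upward over is-a edges, collecting slim hits per level
        seen = {term}
        frontier = deque([term])
        hits: set[str] = set()
        while frontier and not hits:
            level = list(frontier)
            frontier.clear()
            hits = {t for t in level if t in slim}
            if hits:
                break
            for t in level:
                for p in taxonomy.parents(t):
                    if p not in seen:
                        seen.add(p)
                        frontier.append(p)
        mapping[term] = frozenset(hits)
    return SlimMap(slim_terms=slim, mapping=mapping)


def gene_go_profile(
    gene: str,
    annotations: dict[tuple[str, str], str],
    slim_map: SlimMap,
) -> dict[str, int]:
    """Slim-space annotation profile of a gene: slim term -> best tier.

    ``annotations`` maps ``(gene, raw term)`` to an evidence code.
    Annotations with no-source codes are dropped; when one slim term is
    reached from several raw annotations only the strongest (lowest)
    tier is retained.
    """
    profile: dict[str, int] = {}
    for (g, term), code in annotations.items():
        if g != gene:
            continue
        tier = evidence_tier(code)
        if tier is None:
            continue
        for slim_term in slim_map[term]:
            prev = profile.get(slim_term)
            if prev is None or tier < prev:
                profile[slim_term] = tier
    return profile


@dataclass
class GeneFeatureVector:
    """One gene's classifier input row.

    ``go_features`` holds the slim-term weights; ``phenotype_features``
    the patient's phenotype terms (vectorized against the full dataset
    vocabulary at matrix-assembly time).  ``training_weight`` is the
    integer copy count used to replicate the row in the training matrix;
    ``label`` is True for harmful (training only).
    """

    gene: str
    go_features: dict[str, float] = field(default_factory=dict)
    phenotype_features: frozenset[str] = frozenset()
    training_weight: int = 1
    label: bool | None = None


def _contributing_members(
    sub: QuerySubnetwork | None, query: str, k_neighbors: int
) -> list[tuple[str, int]]:
    """(member, rank) pairs for the query (rank 0) plus top-k neighbors."""
    out = [(query, 0)]
    if sub is not None and sub.neighbors and k_neighbors > 0:
        out += [(m, sub.ranks[m]) for m in sub.top_neighbors(k_neighbors)]
    return out


def feature_weights_uniform(
    gene: str,
    subnetwork: QuerySubnetwork | None,
    profiles: dict[str, dict[str, int]],
    k_neighbors: int = 10,
) -> GeneFeatureVector:
    """Indicator weights: 1 for every slim term annotating the gene or
    any of its top-``k`` ranked neighbors."""
    weights: dict[str, float] = {}
    for member, _rank in _contributing_members(subnetwork, gene, k_neighbors):
        for term in profiles.get(member, {}):
            weights[term] = 1.0
    return GeneFeatureVector(gene=gene, go_features=weights)


def feature_weights_network(
    gene: str,
    subnetwork: QuerySubnetwork | None,
    profiles: dict[str, dict[str, int]],
    k_neighbors: int = 10,
) -> GeneFeatureVector:
    """Rank- and evidence-damped weights.

    Each member's surviving annotation of a slim term adds
    ``10**(-rank) * 10**(-tier)``; the query gene contributes at rank 0,
    neighbors at their random-walk rank.
    """
    weights: dict[str, float] = {}
    for member, rank in _contributing_members(subnetwork, gene, k_neighbors):
        for term, tier in profiles.get(member, {}).items():
            weights[term] = weights.get(term, 0.0) + 10.0 ** (-rank) * 10.0 ** (-tier)
    return GeneFeatureVector(gene=gene, go_features=weights)


def read_slim_terms(path: str) -> set[str]:
    """Read a flat file of slim term identifiers, one per line."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
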