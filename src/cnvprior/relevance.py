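"""Phenotype-driven gene relevance and training-copy weights.

A gene's relevance to a patient's phenotypes is the best product, over a
catalog of known gene–phenotype associations, of (a) the functional
similarity between the gene and a catalog gene and (b) the similarity
between the patient's phenotype terms and the catalog entry's
phenotypes — both computed with the information-content measure from
:mod:`cnvprior.ontology`.  Genes scoring zero borrow the best direct
score among their subnetwork neighbors, scaled down by the normalized
inverse Dijkstra distance (one hop, never recursive).

Relevance scores are turned into integer training copy counts so that
every CNV is represented by ~1000 gene rows in the gene classifier's
training matrix, split across its genes proportionally to relevance
(or uniformly, for the phenotype-uniform baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

from .network import QuerySubnetwork
from .ontology import AnnotationGraph, Taxonomy, set_similarity

__all__ = [
    "GenePhenotypeCatalog",
    "RelevanceScore",
    "gene_relevance",
    "training_weights_phenotype",
    "training_weights_uniform",
    "read_catalog",
]

#: Copies representing each CNV in the gene training matrix.
DEFAULT_COPIES_PER_CNV = 1000


@dataclass
class GenePhenotypeCatalog:
    """Known gene -> phenotype-set associations (OMIM/HPO-extract style)."""

    entries: list[tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RelevanceScore:
    gene: str
    phenotypes: frozenset[str]
    score: float
    source: str  # "direct" | "neighbor-fallback"


def _direct_relevance(
    gene_go: frozenset[str],
    patient_phenotypes: frozenset[str],
    catalog: GenePhenotypeCatalog,
    go_tax: Taxonomy,
    go_ag: AnnotationGraph,
    hpo_tax: Taxonomy,
    hpo_ag: AnnotationGraph,
    gene_profiles: dict[str, frozenset[str]],
) -> float:
    best = 0.0
    for cat_gene, cat_phenos in catalog.entries:
        cat_go = gene_profiles.get(cat_gene, frozenset())
        s_go = set_similarity(gene_go, cat_go, go_tax, go_ag)
        if s_go == 0.0:
            continue
        s_ph = set_similarity(patient_phenotypes, cat_phenos, hpo_tax, hpo_ag)
        best = max(best, s_go * s_ph)
    return best


def gene_relevance(
    gene: str,
    patient_phenotypes: frozenset[str] | set[str],
    catalog: GenePhenotypeCatalog,
    go_tax: Taxonomy,
    go_ag: AnnotationGraph,
    hpo_tax: Taxonomy,
    hpo_ag: AnnotationGraph,
    gene_profiles: dict[str, frozenset[str]],
    subnetwork: QuerySubnetwork | None = None,
) -> RelevanceScore:
    """Relevance of ``gene`` to ``patient_phenotypes``.

    ``gene_profiles`` maps gene -> raw function-term set (``GO(g)``).
    When the direct score is zero and a subnetwork is supplied, the
    fallback takes the maximum over neighbors of the neighbor's *direct*
    score times ``1/d`` (the Dijkstra-distance weight normalized to
    (0, 1], so a fallback can never beat the neighbor it borrows from).
    """
    phenos = frozenset(patient_phenotypes)
    args = (catalog, go_tax, go_ag, hpo_tax, hpo_ag, gene_profiles)
    score = _direct_relevance(gene_profiles.get(gene, frozenset()), phenos, *args)
    if score > 0.0 or subnetwork is None:
        return RelevanceScore(gene, phenos, score, "direct")

    best = 0.0
    for nb in subnetwork.neighbors:
        nb_score = _direct_relevance(
            gene_profiles.get(nb, frozenset()), phenos, *args
        )
        d = subnetwork.distances[nb]
        best = max(best, nb_score / d)
    source = "neighbor-fallback" if best > 0.0 else "direct"
    return RelevanceScore(gene, phenos, best, source)


def training_weights_phenotype(
    scores: Sequence[RelevanceScore], copies_per_cnv: int = DEFAULT_COPIES_PER_CNV
) -> dict[str, int]:
    """Copy counts for one CNV's genes, proportional to relevance.

    ``copies(g) = ceil(relevance(g) / sum(relevance) * copies_per_cnv)``;
    the ceiling can overshoot the total by at most one copy per gene.
    A CNV whose genes all score zero gets a single copy per gene.
    """
    if not scores:
        return {}
    total = sum(s.score for s in scores)
    if total == 0.0:
        return {s.gene: 1 for s in scores}
    return {
        s.gene: ceil(s.score / total * copies_per_cnv) if s.score > 0 else 0
        for s in scores
    }


def training_weights_uniform(
    n_genes: int, copies_per_cnv: int = DEFAULT_COPIES_PER_CNV
) -> int:
    """Copies per gene when every gene of the CNV weighs the same."""
    if n_genes == 0:
        raise ValueError("CNV has no genes")
    return ceil(copies_per_cnv / n_genes)


def read_catalog(path: str) -> GenePhenotypeCatalog:
    """Read a tab-separated catalog: gene <TAB> semicolon-joined phenotypes."""
    entries: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            phenos = frozenset(p for p in fields[1].split(";") if p)
            entries.append((fields[0], phenos))
    return GenePhenotypeCatalog(entries=entries)
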