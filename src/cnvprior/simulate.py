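"""Self-contained synthetic resources for every pipeline stage.

The generator emulates, at toy scale, each external resource the
prioritizer consumes: a gene-function ontology with a slim cut, a
phenotype ontology with disorder annotations, gene models on a small
multi-chromosome genome, evidence-coded gene annotations, a weighted
interaction network, a gene–phenotype catalog, benign-region study sets,
and a patient cohort of labeled CNVs.

The harmful signal is *planted*: a few slim function terms are declared
pathogenic, a handful of "disease genes" are annotated below them (with
experimental evidence) and wired into a strong network module, harmful
CNVs are placed over those genes with probability ``effect_strength``,
drawn longer on average than benign CNVs, and left out of the
benign-region catalogs, while benign CNVs avoid the disease genes and
are well covered by those catalogs.  The catalog links the disease
genes to the cohort's phenotype terms so phenotype relevance is
informative.  Everything is a pure function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import CNVRecord, DGVStudySet, GeneModels
from .classify import Resources
from .features import build_slim_map
from .ontology import AnnotationGraph, Taxonomy, propagate_annotations
from .network import WeightedGeneNetwork

__all__ = [
    "FixtureConfig",
    "Bundle",
    "make_taxonomy",
    "make_cohort",
    "make_bundle",
    "write_bundle",
    "make_clinical_scale_table",
]

TIER1_POOL = ("IDA", "IMP", "TAS")
TIER2_POOL = ("IEA", "ISS", "IBA")


@dataclass
class FixtureConfig:
    """Knobs of the synthetic world.  Defaults are the study conditions
    used throughout the test-suite and the acceptance script."""

    seed: int = 0
    n_go_terms: int = 60
    n_hpo_terms: int = 24
    n_genes: int = 80
    n_patients: int = 32
    n_cnvs: int = 64
    benign_ratio: float = 15.0        # clinical benign:harmful excess
    effect_strength: float = 0.95     # P(harmful CNV spans a disease gene)
    n_planted_terms: int = 3
    n_planted_genes: int = 8
    annotation_noise: float = 0.1     # P(extra random annotation per gene)
    n_disorders: int = 20
    n_chromosomes: int = 4
    chromosome_length: int = 10_000_000
    n_dgv_studies: int = 3
    dgv_benign_coverage: float = 0.9  # per-study P(benign CNV catalogued)
    dgv_harmful_coverage: float = 0.05
    # length distributions (log10 bp): harmful CNVs run longer (clinical
    # cohorts show the same qualitative trend)
    benign_log10_length: tuple[float, float] = (4.5, 0.35)
    harmful_log10_length: tuple[float, float] = (5.4, 0.35)

    def __post_init__(self) -> None:
        if self.n_go_terms < 5 or self.n_hpo_terms < 5:
            raise ValueError("taxonomies need at least 5 terms")
        if self.n_patients < 4 or self.n_cnvs < 8:
            raise ValueError("cohort too small to split")
        if not (0 <= self.effect_strength <= 1):
            raise ValueError("effect_strength must be in [0, 1]")
        if self.benign_ratio <= 0:
            raise ValueError("benign_ratio must be positive")


@dataclass
class Bundle:
    """Everything one experiment needs, in memory."""

    config: FixtureConfig
    go_tax: Taxonomy
    go_slim: frozenset[str]
    hpo_tax: Taxonomy
    hpo_pairs: list[tuple[str, str]]           # (phenotype term, disorder)
    gene_records: list[tuple[str, int, int, str]]
    go_evidence: dict[tuple[str, str], str]    # (gene, term) -> code
    network: WeightedGeneNetwork
    catalog_entries: list[tuple[str, frozenset[str]]]
    dgv_regions: list[tuple[str, str, int, int]]  # study, chrom, start, end
    cnvs: list[CNVRecord]
    planted_terms: frozenset[str]
    planted_genes: frozenset[str]

    def resources(self) -> Resources:
        from .relevance import GenePhenotypeCatalog

        go_raw = AnnotationGraph.from_pairs(
            [(term, gene) for (gene, term) in self.go_evidence]
        )
        go_ag = propagate_annotations(self.go_tax, go_raw)
        hpo_raw = AnnotationGraph.from_pairs(self.hpo_pairs)
        hpo_ag = propagate_annotations(self.hpo_tax, hpo_raw)
        studies: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for study, chrom, start, end in self.dgv_regions:
            studies.setdefault(study, {}).setdefault(chrom, []).append((start, end))
        return Resources(
            go_tax=self.go_tax,
            go_ag_raw=go_raw,
            go_ag=go_ag,
            go_evidence=self.go_evidence,
            slim_map=build_slim_map(self.go_tax, self.go_slim),
            hpo_tax=self.hpo_tax,
            hpo_ag=hpo_ag,
            network=self.network,
            catalog=GenePhenotypeCatalog(entries=list(self.catalog_entries)),
            gene_models=GeneModels(self.gene_records),
            dgv=DGVStudySet(studies),
        )


# ---------------------------------------------------------------------------
# Taxonomies

def make_taxonomy(
    rng: np.random.Generator,
    n_terms: int,
    prefix: str,
    diamond_fraction: float = 0.25,
) -> tuple[Taxonomy, frozenset[str]]:
    """Rooted DAG of ``n_terms`` terms with a designated slim layer.

    Tiny taxonomies (<= 5 terms) degenerate to a path whose slim layer
    is the root's child.  Larger ones place a slim layer directly under
    the root and hang the remaining terms below it, giving a fraction of
    them a second parent so common-ancestor queries see real diamonds.
    """
    ids = [f"{prefix}{i:04d}" for i in range(n_terms)]
    root = ids[0]
    edges: list[tuple[str, str]] = []
    if n_terms <= 5:
        for child, parent in zip(ids[1:], ids[:-1]):
            edges.append((child, parent))
        slim = frozenset([ids[1]])
        return Taxonomy(ids, edges), slim

    n_slim = max(3, round(n_terms * 0.18))
    slim_ids = ids[1 : 1 + n_slim]
    for s in slim_ids:
        edges.append((s, root))
    for i in range(1 + n_slim, n_terms):
        term = ids[i]
        # primary parent: any earlier non-root term (keeps edges acyclic)
        parent = ids[int(rng.integers(1, i))]
        edges.append((term, parent))
        if rng.random() < diamond_fraction:
            second = ids[int(rng.integers(1, i))]
            if second != parent:
                edges.append((term, second))
    return Taxonomy(ids, edges), frozenset(slim_ids)


# ---------------------------------------------------------------------------
# Cohort

def _place_genes(
    rng: np.random.Generator, cfg: FixtureConfig
) -> list[tuple[str, int, int, str]]:
    records = []
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    g = 0
    for c in range(1, cfg.n_chromosomes + 1):
        pos = int(rng.integers(50_000, 150_000))
        for _ in range(per_chrom):
            if g >= cfg.n_genes:
                break
            length = int(rng.integers(5_000, 50_000))
            records.append((f"chr{c}", pos, pos + length, f"G{g:03d}"))
            pos += length + int(rng.integers(20_000, 80_000))
            g += 1
    return records


def _descendants_of(tax: Taxonomy, terms: frozenset[str]) -> set[str]:
    return {t for t in tax.terms if tax.ancestors(t) & terms}


def make_cohort(cfg: FixtureConfig) -> "Bundle":
    """Generate the full resource bundle for one seeded configuration."""
    rng = np.random.default_rng(cfg.seed)

    go_tax, go_slim = make_taxonomy(rng, cfg.n_go_terms, "F")
    hpo_tax, _ = make_taxonomy(rng, cfg.n_hpo_terms, "P")

    planted_terms = frozenset(
        sorted(go_slim)[i] for i in rng.choice(len(go_slim), cfg.n_planted_terms, replace=False)
    )
    planted_pool = sorted(_descendants_of(go_tax, planted_terms))
    # per-branch pools so every planted term carries annotation mass
    planted_branches = [
        sorted(_descendants_of(go_tax, frozenset([t]))) for t in sorted(planted_terms)
    ]
    background_pool = sorted(set(go_tax.terms) - set(planted_pool) - set(go_tax.roots()))

    gene_records = _place_genes(rng, cfg)
    genes = [g for _, _, _, g in gene_records]
    planted_genes = frozenset(
        genes[i] for i in rng.choice(len(genes), cfg.n_planted_genes, replace=False)
    )

    # --- annotations -------------------------------------------------------
    go_evidence: dict[tuple[str, str], str] = {}

    def annotate(gene: str, term: str, tier1_prob: float) -> None:
        pool = TIER1_POOL if rng.random() < tier1_prob else TIER2_POOL
        go_evidence[(gene, term)] = str(pool[int(rng.integers(len(pool)))])

    planted_cursor = 0
    for gene in genes:
        n_ann = int(rng.integers(2, 6))
        if gene in planted_genes:
            for _ in range(max(2, n_ann // 2)):
                branch = planted_branches[planted_cursor % len(planted_branches)]
                planted_cursor += 1
                annotate(gene, branch[int(rng.integers(len(branch)))], 0.8)
            for _ in range(n_ann - max(2, n_ann // 2)):
                annotate(gene, background_pool[int(rng.integers(len(background_pool)))], 0.5)
        else:
            for _ in range(n_ann):
                annotate(gene, background_pool[int(rng.integers(len(background_pool)))], 0.5)
        if rng.random() < cfg.annotation_noise:
            # noise: any term at all, planted branch included
            all_pool = planted_pool + background_pool
            annotate(gene, all_pool[int(rng.integers(len(all_pool)))], 0.3)

    # --- network -----------------------------------------------------------
    net = WeightedGeneNetwork()
    for g in genes:
        net.add_node(g)
    planted_list = sorted(planted_genes)
    for i, a in enumerate(planted_list):           # strong disease module
        for b in planted_list[i + 1 :]:
            if rng.random() < 0.6:
                net.add_edge(a, b, float(rng.uniform(0.7, 1.0)))
    non_planted_genes = [g for g in genes if g not in planted_genes]
    for a in planted_list:                         # disease genes are hubs:
        k = int(rng.integers(4, 8))                # strong links to bystanders
        for i in rng.choice(len(non_planted_genes), k, replace=False):
            b = non_planted_genes[int(i)]
            if not net.graph().has_edge(a, b):
                net.add_edge(a, b, float(rng.uniform(0.5, 0.9)))
    n_bg_edges = cfg.n_genes * 3
    for _ in range(n_bg_edges):                    # background interactome
        i, j = rng.choice(cfg.n_genes, 2, replace=False)
        a, b = genes[int(i)], genes[int(j)]
        if a != b and not net.graph().has_edge(a, b):
            net.add_edge(a, b, float(rng.uniform(0.05, 0.6)))

    # --- phenotypes, disorders, catalog ------------------------------------
    non_root_ph = sorted(set(hpo_tax.terms) - hpo_tax.roots())
    clinical_ph = [non_root_ph[i] for i in rng.choice(len(non_root_ph), 3, replace=False)]
    hpo_pairs: list[tuple[str, str]] = []
    for d in range(cfg.n_disorders):
        k = int(rng.integers(2, 5))
        for i in rng.choice(len(non_root_ph), k, replace=False):
            hpo_pairs.append((non_root_ph[int(i)], f"D{d:03d}"))
    # make sure the clinical phenotype terms carry annotation evidence
    for i, p in enumerate(clinical_ph):
        hpo_pairs.append((p, f"D{i:03d}"))

    catalog_entries: list[tuple[str, frozenset[str]]] = []
    for g in planted_list:                         # known disease genes
        k = int(rng.integers(1, 3))
        phenos = frozenset(
            clinical_ph[int(i)] for i in rng.choice(len(clinical_ph), k, replace=False)
        )
        catalog_entries.append((g, phenos))
    decoys = [g for g in genes if g not in planted_genes]
    for i in rng.choice(len(decoys), 6, replace=False):  # uninformative decoys
        phenos = frozenset(
            non_root_ph[int(j)] for j in rng.choice(len(non_root_ph), 2, replace=False)
        )
        catalog_entries.append((decoys[int(i)], phenos))

    # --- patients and CNVs --------------------------------------------------
    pheno_weights = np.array([0.7, 0.2, 0.1])
    patient_phenos: list[frozenset[str]] = []
    for _ in range(cfg.n_patients):
        k = 1 + int(rng.random() < 0.3)
        idx = rng.choice(3, size=k, replace=False, p=pheno_weights)
        patient_phenos.append(frozenset(clinical_ph[int(i)] for i in idx))

    n_harmful = max(2, round(cfg.n_cnvs / (1 + cfg.benign_ratio)))
    n_benign = cfg.n_cnvs - n_harmful
    gene_by_id = {g: (c, s, e) for c, s, e, g in gene_records}

    def draw_length(harmful: bool) -> int:
        mu, sigma = cfg.harmful_log10_length if harmful else cfg.benign_log10_length
        return max(1_000, int(round(10 ** rng.normal(mu, sigma))))

    def random_interval(length: int) -> tuple[str, int, int]:
        chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
        start = int(rng.integers(0, cfg.chromosome_length - length))
        return chrom, start, start + length

    def contains_planted(chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and s < end and start < e
            for g in planted_genes
            for c, s, e in [gene_by_id[g]]
        )

    cnvs: list[CNVRecord] = []
    non_planted = [g for g in genes if g not in planted_genes]

    def cover_gene(g: str, length: int) -> tuple[str, int, int]:
        chrom, gs, ge = gene_by_id[g]
        lo = max(0, ge - length)
        start = int(rng.integers(lo, gs + 1)) if gs + 1 > lo else lo
        end = start + length
        if end <= gs:  # CNV shorter than the offset: anchor at the gene start
            start, end = gs, gs + length
        return chrom, start, end

    def add_cnv(harmful: bool, idx: int) -> None:
        patient = idx % cfg.n_patients
        length = draw_length(harmful)
        if harmful and rng.random() < cfg.effect_strength:
            g = planted_list[int(rng.integers(len(planted_list)))]
            chrom, start, end = cover_gene(g, length)
        elif rng.random() < 0.9:
            # gene-rich call over an ordinary gene, clear of the disease module
            for _ in range(100):
                g = non_planted[int(rng.integers(len(non_planted)))]
                chrom, start, end = cover_gene(g, length)
                if not contains_planted(chrom, start, end):
                    break
        else:
            # occasional gene-desert call
            for _ in range(200):
                chrom, start, end = random_interval(length)
                if not contains_planted(chrom, start, end):
                    break
        cnvs.append(
            CNVRecord(
                chromosome=chrom,
                start=start,
                end=end,
                type="DEL" if rng.random() < 0.6 else "DUP",
                phenotypes=patient_phenos[patient],
                label=harmful,
                patient=f"PT{patient:03d}",
            )
        )

    for i in range(n_harmful):
        add_cnv(True, i)
    for i in range(n_benign):
        add_cnv(False, n_harmful + i)

    # --- benign-region studies ----------------------------------------------
    dgv_regions: list[tuple[str, str, int, int]] = []
    for s in range(cfg.n_dgv_studies):
        study = f"STUDY{s}"
        for cnv in cnvs:
            cover_p = (
                cfg.dgv_harmful_coverage if cnv.label else cfg.dgv_benign_coverage
            )
            if rng.random() < cover_p:
                pad = int(0.1 * cnv.length)
                dgv_regions.append(
                    (
                        study,
                        cnv.chromosome,
                        max(0, cnv.start - int(rng.integers(0, pad + 1))),
                        cnv.end + int(rng.integers(0, pad + 1)),
                    )
                )

    return Bundle(
        config=cfg,
        go_tax=go_tax,
        go_slim=go_slim,
        hpo_tax=hpo_tax,
        hpo_pairs=hpo_pairs,
        gene_records=gene_records,
        go_evidence=go_evidence,
        network=net,
        catalog_entries=catalog_entries,
        dgv_regions=dgv_regions,
        cnvs=cnvs,
        planted_terms=planted_terms,
        planted_genes=planted_genes,
    )


def make_bundle(seed: int = 0, **kwargs) -> Bundle:
    """Convenience: cohort bundle from a seed plus config overrides."""
    return make_cohort(FixtureConfig(seed=seed, **kwargs))


def experiment_config(**overrides):
    """Run configuration matched to the synthetic cohorts.

    The toy interactome is generated already thinned (a few edges per
    gene, unlike a dense genome-scale composite network), so the
    edge-filter fraction is raised to 0.5 to preserve a comparable
    post-filter density; 50 trees are ample for the toy feature count.
    All other parameters keep their canonical defaults.
    """
    from .config import RunConfig

    defaults: dict = dict(edge_fraction=0.5, rf_trees=50, runs=20)
    defaults.update(overrides)
    return RunConfig(**defaults)


# ---------------------------------------------------------------------------
# Writers (plain-text formats accepted by the readers)

def _write_obo(path: str, tax: Taxonomy, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"format-version: 1.2\nontology: {name}\n\n")
        for term in sorted(tax.terms):
            fh.write(f"[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(tax.parents(term)):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


def write_bundle(bundle: Bundle, outdir: str) -> dict[str, str]:
    """Write every resource as the plain-text format its reader accepts.

    Returns the mapping of resource name to file path.  Byte-identical
    across calls for the same config.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "go_obo": "functions.obo",
        "hpo_obo": "phenotypes.obo",
        "slim_terms": "slim_terms.txt",
        "go_annotations": "gene_annotations.gaf.tsv",
        "hpo_annotations": "phenotype_annotations.tsv",
        "network": "network_edges.tsv",
        "catalog": "gene_phenotype_catalog.tsv",
        "gene_models": "gene_models.bed",
        "dgv_table": "benign_regions.tsv",
        "cnv_table": "cnv_table.tsv",
    }.items()}

    _write_obo(paths["go_obo"], bundle.go_tax, "synthetic-gene-functions")
    _write_obo(paths["hpo_obo"], bundle.hpo_tax, "synthetic-phenotypes")
    with open(paths["slim_terms"], "w") as fh:
        fh.writelines(t + "\n" for t in sorted(bundle.go_slim))
    with open(paths["go_annotations"], "w") as fh:
        for (gene, term), code in sorted(bundle.go_evidence.items()):
            fh.write(f"{gene}\t{term}\t{code}\n")
    with open(paths["hpo_annotations"], "w") as fh:
        for term, disorder in sorted(bundle.hpo_pairs):
            fh.write(f"{disorder}\t{term}\n")
    with open(paths["network"], "w") as fh:
        for a, b, w in sorted(bundle.network.edges()):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
    with open(paths["catalog"], "w") as fh:
        for gene, phenos in sorted(bundle.catalog_entries):
            fh.write(f"{gene}\t{';'.join(sorted(phenos))}\n")
    with open(paths["gene_models"], "w") as fh:
        for chrom, start, end, gene in bundle.gene_records:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
    with open(paths["dgv_table"], "w") as fh:
        for study, chrom, start, end in bundle.dgv_regions:
            fh.write(f"{study}\t{chrom}\t{start}\t{end}\n")
    with open(paths["cnv_table"], "w") as fh:
        fh.write("chromosome\tstart\tend\ttype\tphenotype\tclassification\tpatient\n")
        for c in bundle.cnvs:
            label = "HARMFUL" if c.label else "BENIGN"
            fh.write(
                f"{c.chromosome}\t{c.start}\t{c.end}\t{c.type}\t"
                f"{';'.join(sorted(c.phenotypes))}\t{label}\t{c.patient}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# Clinical-scale stand-in table

def make_clinical_scale_table(path: str, seed: int = 0) -> None:
    """Write a synthetic CNV table shaped like a clinical CGH-array cohort.

    This is a *synthetic stand-in* for a diagnostic-laboratory dataset:
    2,643 CNVs from 140 patients, 162 labeled HARMFUL and 2,481 BENIGN,
    every patient carrying at least one harmful call, phenotypes
    dominated by developmental delay (119 patients) and facial
    dysmorphism (10 patients), with seven rarer phenotypes covering the
    remainder.  Coordinates and types are random; only the table's
    shape and label/phenotype composition are meaningful.
    """
    rng = np.random.default_rng(seed)
    n_patients, n_harmful, n_benign = 140, 162, 2481
    phenos = (
        ["developmental delay"] * 119
        + ["facial dysmorphism"] * 10
        + ["autism", "cleft palate", "congenital heart defect", "failure to thrive"]
        + ["microcephaly", "seizures", "short stature"]
        + ["autism", "cleft palate", "congenital heart defect", "failure to thrive"]
    )
    assert len(phenos) == n_patients
    # one harmful CNV per patient, the surplus spread at random
    harmful_per_patient = np.ones(n_patients, dtype=int)
    for i in rng.choice(n_patients, n_harmful - n_patients, replace=True):
        harmful_per_patient[i] += 1
    benign_per_patient = np.zeros(n_patients, dtype=int)
    for i in rng.choice(n_patients, n_benign, replace=True):
        benign_per_patient[i] += 1

    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\ttype\tphenotype\tclassification\n")
        for p in range(n_patients):
            for harmful, count in ((True, harmful_per_patient[p]), (False, benign_per_patient[p])):
                for _ in range(count):
                    chrom = f"chr{int(rng.integers(1, 23))}"
                    length = int(round(10 ** rng.normal(5.2 if harmful else 4.4, 0.5)))
                    start = int(rng.integers(1, 100_000_000))
                    cnv_type = "DEL" if rng.random() < 0.6 else "DUP"
                    label = "HARMFUL" if harmful else "BENIGN"
                    fh.write(
                        f"{chrom}\t{start}\t{start + max(1000, length)}\t{cnv_type}\t"
                        f"{phenos[p]}\t{label}\n"
                    )
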