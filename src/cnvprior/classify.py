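"""Two-stage classification: gene-level Random Forest, CNV-level Naive Bayes.

Stage one trains a Random Forest on gene rows (slim-function weights
plus the patient phenotype indicator block), with each CNV's label
propagated verbatim to its genes and each gene replicated according to
its phenotype-relevance copy count.  Stage two reduces every CNV to
three features — the logical OR of its genes' "causative" calls, its
length, and its benign-catalog overlap score — and fits a Naive Bayes
with a Bernoulli likelihood for the boolean and Gaussian likelihoods
for log10(length) and the overlap score.

Evaluation follows a three-pool protocol: half the data trains the gene
classifier, a quarter tests it and trains the CNV classifier, and the
final quarter tests the CNV classifier.  The *balanced* regime draws
phenotype-matched case/control quads of CNVs; the *unbalanced* regime
splits whole patients, preserving the clinical excess of benign calls.
Metrics are averaged over independent runs (20 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .annotation import CNVRecord, GeneModels, DGVStudySet, dgv_frequency, map_cnv_genes
from .config import RunConfig, run_seeds
from .features import (
    SlimMap,
    feature_weights_network,
    feature_weights_uniform,
    gene_go_profile,
)
from .network import QuerySubnetwork, WeightedGeneNetwork, build_subnetwork, filter_top_edges, random_walk_ranks
from .ontology import AnnotationGraph, Taxonomy
from .relevance import (
    GenePhenotypeCatalog,
    RelevanceScore,
    gene_relevance,
    training_weights_phenotype,
    training_weights_uniform,
)

__all__ = [
    "Resources",
    "Split",
    "balanced_split",
    "unbalanced_split",
    "train_gene_classifier",
    "predict_causative",
    "CNVFeatureRow",
    "CNVNaiveBayes",
    "train_cnv_classifier",
    "EvalMetrics",
    "EvalReport",
    "evaluate",
    "Pipeline",
    "run_experiment",
    "permute_labels",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Resources

@dataclass
class Resources:
    """All external knowledge the pipeline consumes, already parsed."""

    go_tax: Taxonomy
    go_ag_raw: AnnotationGraph            # direct gene annotations
    go_ag: AnnotationGraph                # propagated (for IC)
    go_evidence: dict[tuple[str, str], str]
    slim_map: SlimMap
    hpo_tax: Taxonomy
    hpo_ag: AnnotationGraph               # propagated phenotype->disorder
    network: WeightedGeneNetwork          # unfiltered
    catalog: GenePhenotypeCatalog
    gene_models: GeneModels
    dgv: DGVStudySet


# ---------------------------------------------------------------------------
# Splits

@dataclass
class Split:
    gene_train: list[CNVRecord]
    cnv_train: list[CNVRecord]            # doubles as the gene test pool
    cnv_test: list[CNVRecord]

    def pools(self) -> tuple[list[CNVRecord], list[CNVRecord], list[CNVRecord]]:
        return self.gene_train, self.cnv_train, self.cnv_test


def balanced_split(cnvs: list[CNVRecord], seed: int) -> Split:
    """Phenotype-matched case/control split into 50 / 25 / 25 pools.

    Phenotypes are swept in order of decreasing case count; while a
    phenotype still has two unused cases (harmful) and two unused
    controls (benign), a quad is drawn at random and distributed so that
    every pool keeps a 1:1 class ratio and the pools fill in 2:1:1
    proportion.  CNVs never drawn by the sweep are left out of the run.
    """
    rng = np.random.default_rng(seed)
    for c in cnvs:
        if c.label is None:
            raise ValueError("balanced_split requires labeled CNVs")
    phenotypes = sorted(
        {p for c in cnvs for p in c.phenotypes},
        key=lambda p: (-sum(1 for c in cnvs if c.label and p in c.phenotypes), p),
    )
    used: set[int] = set()
    pools: tuple[list[CNVRecord], ...] = ([], [], [])
    quad_parity = 0
    for pheno in phenotypes:
        while True:
            cases = [i for i, c in enumerate(cnvs)
                     if i not in used and c.label and pheno in c.phenotypes]
            controls = [i for i, c in enumerate(cnvs)
                        if i not in used and not c.label and pheno in c.phenotypes]
            if len(cases) < 2 or len(controls) < 2:
                break
            c1, c2 = rng.choice(cases, size=2, replace=False)
            b1, b2 = rng.choice(controls, size=2, replace=False)
            used.update((c1, c2, b1, b2))
            pools[0].extend([cnvs[c1], cnvs[b1]])
            other = 1 if quad_parity == 0 else 2
            pools[other].extend([cnvs[c2], cnvs[b2]])
            quad_parity ^= 1
    if not pools[0]:
        raise ValueError(
            "no phenotype offers two cases and two controls; balanced split impossible"
        )
    return Split(*pools)


def unbalanced_split(cnvs: list[CNVRecord], seed: int) -> Split:
    """Whole-patient split into 50 / 25 / 25 pools by CNV count.

    Every CNV of a patient lands in the same pool, so the test pool
    keeps the cohort's natural benign:harmful imbalance.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[CNVRecord]] = {}
    for c in cnvs:
        if c.patient is None:
            raise ValueError("unbalanced_split requires patient identifiers")
        by_patient.setdefault(c.patient, []).append(c)
    patients = sorted(by_patient)
    if len(patients) < 4:
        raise ValueError(f"need >=4 patients for an unbalanced split, got {len(patients)}")
    order = list(rng.permutation(patients))
    total = len(cnvs)
    targets = (0.5 * total, 0.25 * total, 0.25 * total)
    pools: tuple[list[CNVRecord], ...] = ([], [], [])
    for p in order:
        deficits = [targets[i] - len(pools[i]) for i in range(3)]
        i = int(np.argmax(deficits))
        pools[i].extend(by_patient[p])
    return Split(*pools)


def permute_labels(cnvs: list[CNVRecord], seed: int) -> list[CNVRecord]:
    """Copy of the cohort with labels randomly reassigned (null model)."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    labels = [c.label for c in cnvs]
    perm = rng.permutation(len(labels))
    return [replace(c, label=labels[perm[i]]) for i, c in enumerate(cnvs)]


# ---------------------------------------------------------------------------
# Gene classifier

def train_gene_classifier(
    X: np.ndarray, y: np.ndarray, config: RunConfig, seed: int
) -> RandomForestClassifier:
    """Fit the gene-level Random Forest (rejects single-class input)."""
    if len(np.unique(y)) < 2:
        raise ValueError("gene training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features=config.rf_max_features,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def predict_causative(
    model: RandomForestClassifier, gene_matrix: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Per-gene harmful calls and their logical OR (the CNV flag).

    An empty gene matrix (gene-less CNV) yields no calls and a False flag.
    """
    if gene_matrix.shape[0] == 0:
        return np.zeros(0, dtype=bool), False
    if gene_matrix.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature-space mismatch: model expects {model.n_features_in_} "
            f"features, got {gene_matrix.shape[1]}"
        )
    calls = model.predict(gene_matrix).astype(bool)
    return calls, bool(calls.any())


# ---------------------------------------------------------------------------
# CNV classifier

@dataclass
class CNVFeatureRow:
    causative_gene: bool
    length: int
    dgv: float
    label: bool | None = None


_VAR_FLOOR = 1e-9


class CNVNaiveBayes:
    """Naive Bayes over the three CNV features.

    Bernoulli likelihood (Laplace-smoothed) for ``causative_gene``;
    Gaussian likelihoods for ``log10(length)`` and for the benign-
    overlap score, with a small variance floor for degenerate
    (constant) features.  ``features`` selects any subset for ablation.
    """

    def __init__(self, features: tuple[str, ...] = ("gene", "length", "dgv")):
        self.features = tuple(features)
        self._fitted = False

    @staticmethod
    def _numeric(rows: list[CNVFeatureRow], name: str) -> np.ndarray:
        if name == "length":
            return np.log10(np.array([r.length for r in rows], dtype=float))
        return np.array([r.dgv for r in rows], dtype=float)

    def fit(self, rows: list[CNVFeatureRow]) -> "CNVNaiveBayes":
        labels = np.array([bool(r.label) for r in rows])
        if len(set(labels.tolist())) < 2:
            raise ValueError("CNV training set contains a single class")
        self.classes_ = (False, True)
        n = len(rows)
        self.log_prior_ = {
            cls: math.log((labels == cls).sum() / n) for cls in self.classes_
        }
        self.bernoulli_: dict[bool, float] = {}
        self.gauss_: dict[str, dict[bool, tuple[float, float]]] = {}
        for cls in self.classes_:
            mask = labels == cls
            if "gene" in self.features:
                flags = np.array([r.causative_gene for r in rows])[mask]
                self.bernoulli_[cls] = (flags.sum() + 1) / (mask.sum() + 2)
        for name in self.features:
            if name == "gene":
                continue
            per_class: dict[bool, tuple[float, float]] = {}
            vals = self._numeric(rows, name)
            for cls in self.classes_:
                v = vals[labels == cls]
                per_class[cls] = (float(v.mean()), max(float(v.var()), _VAR_FLOOR))
            self.gauss_[name] = per_class
        self._fitted = True
        return self

    def _joint_log_likelihood(self, rows: list[CNVFeatureRow]) -> np.ndarray:
        if not self._fitted:
            raise ValueError("model is not fitted")
        n = len(rows)
        jll = np.zeros((n, 2))
        for j, cls in enumerate(self.classes_):
            jll[:, j] = self.log_prior_[cls]
            if "gene" in self.features:
                p = self.bernoulli_[cls]
                flags = np.array([r.causative_gene for r in rows])
                jll[:, j] += np.where(flags, math.log(p), math.log(1 - p))
            for name, per_class in self.gauss_.items():
                mu, var = per_class[cls]
                x = self._numeric(rows, name)
                jll[:, j] += -0.5 * (math.log(2 * math.pi * var) + (x - mu) ** 2 / var)
        return jll

    def predict_log_proba(self, rows: list[CNVFeatureRow]) -> np.ndarray:
        jll = self._joint_log_likelihood(rows)
        log_norm = np.logaddexp(jll[:, 0], jll[:, 1])
        return jll - log_norm[:, None]

    def predict(self, rows: list[CNVFeatureRow]) -> np.ndarray:
        jll = self._joint_log_likelihood(rows)
        return jll[:, 1] > jll[:, 0]

    def conditional_log_likelihood(self, rows: list[CNVFeatureRow]) -> float:
        """Sum of log P(label | features) over labeled rows."""
        logp = self.predict_log_proba(rows)
        idx = np.array([int(bool(r.label)) for r in rows])
        return float(logp[np.arange(len(rows)), idx].sum())


def train_cnv_classifier(
    rows: list[CNVFeatureRow], features: tuple[str, ...] = ("gene", "length", "dgv")
) -> CNVNaiveBayes:
    return CNVNaiveBayes(features=features).fit(rows)


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class EvalMetrics:
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False


@dataclass
class EvalReport:
    runs: list[EvalMetrics]
    seeds: list[int]
    feature_importances: dict[str, float] = field(default_factory=dict)

    @property
    def mean_precision(self) -> float:
        return float(np.mean([r.precision for r in self.runs]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([r.recall for r in self.runs]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([r.f1 for r in self.runs]))

    def to_dict(self) -> dict:
        return {
            "runs": [vars(r) for r in self.runs],
            "seeds": list(self.seeds),
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f1": self.mean_f1,
        }


def evaluate(predictions: np.ndarray | list, labels: np.ndarray | list) -> EvalMetrics:
    """Precision / recall / F on the harmful (positive) class.

    With zero predicted positives precision is undefined; it is reported
    as 0 with ``undefined_precision`` set.
    """
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("prediction/label vectors differ in length")
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvalMetrics(precision, recall, f1, undefined_precision=undefined)


# ---------------------------------------------------------------------------
# End-to-end pipeline

class Pipeline:
    """Caches per-gene subnetworks, profiles and feature weights for one
    (resources, config) pair, and drives the two classification stages."""

    def __init__(self, resources: Resources, config: RunConfig):
        self.res = resources
        self.cfg = config
        self.filtered = filter_top_edges(resources.network, config.edge_fraction)
        self._subnets: dict[str, QuerySubnetwork | None] = {}
        self._profiles: dict[str, dict[str, int]] = {}
        self._go_weights: dict[str, dict[str, float]] = {}
        self._relevance: dict[tuple[str, frozenset[str]], RelevanceScore] = {}
        self._gene_go: dict[str, frozenset[str]] = {}
        for (gene, term) in resources.go_evidence:
            self._gene_go.setdefault(gene, frozenset())
        for (gene, term) in resources.go_evidence:
            self._gene_go[gene] = self._gene_go[gene] | {term}
        self.slim_order = sorted(resources.slim_map.slim_terms)
        self.pheno_vocab: list[str] = []

    def set_phenotype_vocabulary(self, cnvs: list[CNVRecord]) -> None:
        self.pheno_vocab = sorted({p for c in cnvs for p in c.phenotypes})

    @property
    def feature_names(self) -> list[str]:
        return [f"GO:{t}" for t in self.slim_order] + [f"HP:{p}" for p in self.pheno_vocab]

    # -- cached primitives ---------------------------------------------------

    def profile(self, gene: str) -> dict[str, int]:
        if gene not in self._profiles:
            self._profiles[gene] = gene_go_profile(
                gene, self.res.go_evidence, self.res.slim_map
            )
        return self._profiles[gene]

    def subnetwork(self, gene: str) -> QuerySubnetwork | None:
        if gene not in self._subnets:
            if gene not in self.filtered or not self.filtered.neighbors(gene):
                self._subnets[gene] = None
            else:
                sub = build_subnetwork(self.filtered, gene, self.cfg.subnetwork_size)
                if sub.neighbors:
                    random_walk_ranks(
                        sub,
                        alpha=self.cfg.restart_alpha,
                        tol=self.cfg.walk_tol,
                        max_iter=self.cfg.walk_max_iter,
                    )
                self._subnets[gene] = sub
        return self._subnets[gene]

    def go_weights(self, gene: str) -> dict[str, float]:
        if gene not in self._go_weights:
            sub = self.subnetwork(gene)
            profiles = {gene: self.profile(gene)}
            if sub is not None:
                for m in sub.neighbors:
                    profiles[m] = self.profile(m)
            if self.cfg.feature_weighting == "network-weighted":
                fv = feature_weights_network(gene, sub, profiles, self.cfg.k_neighbors)
            else:
                fv = feature_weights_uniform(gene, sub, profiles, self.cfg.k_neighbors)
            self._go_weights[gene] = fv.go_features
        return self._go_weights[gene]

    def relevance(self, gene: str, phenotypes: frozenset[str]) -> RelevanceScore:
        key = (gene, phenotypes)
        if key not in self._relevance:
            self._relevance[key] = gene_relevance(
                gene,
                phenotypes,
                self.res.catalog,
                self.res.go_tax,
                self.res.go_ag,
                self.res.hpo_tax,
                self.res.hpo_ag,
                self._gene_go,
                subnetwork=self.subnetwork(gene),
            )
        return self._relevance[key]

    # -- matrix assembly -----------------------------------------------------

    def vectorize(
        self, items: list[tuple[str, frozenset[str]]]
    ) -> np.ndarray:
        """Rows for (gene, patient phenotype set) pairs."""
        slim_idx = {t: i for i, t in enumerate(self.slim_order)}
        off = len(self.slim_order)
        ph_idx = {p: off + i for i, p in enumerate(self.pheno_vocab)}
        X = np.zeros((len(items), off + len(self.pheno_vocab)))
        for r, (gene, phenos) in enumerate(items):
            for term, w in self.go_weights(gene).items():
                if term in slim_idx:
                    X[r, slim_idx[term]] = w
            for p in phenos:
                if p in ph_idx:
                    X[r, ph_idx[p]] = 1.0
        return X

    def gene_training_rows(
        self, cnvs: list[CNVRecord]
    ) -> tuple[list[tuple[str, frozenset[str]]], list[bool], list[int]]:
        """(gene, phenotypes) items, labels and copy counts, one entry per
        (CNV, gene) instance, before replication."""
        items: list[tuple[str, frozenset[str]]] = []
        labels: list[bool] = []
        copies: list[int] = []
        for cnv in cnvs:
            genes = self.cnv_genes(cnv)
            if not genes:
                continue
            if self.cfg.gene_weighting == "phenotype-weighted":
                scores = [self.relevance(g, cnv.phenotypes) for g in genes]
                counts = training_weights_phenotype(scores, self.cfg.copies_per_cnv)
            else:
                per = training_weights_uniform(len(genes), self.cfg.copies_per_cnv)
                counts = {g: per for g in genes}
            for g in genes:
                c = counts.get(g, 0)
                if c <= 0:
                    continue
                items.append((g, cnv.phenotypes))
                labels.append(bool(cnv.label))
                copies.append(c)
        return items, labels, copies

    def cnv_genes(self, cnv: CNVRecord) -> list[str]:
        if not cnv.genes:
            cnv.genes = map_cnv_genes(cnv, self.res.gene_models)
        return cnv.genes

    def cnv_feature_rows(
        self, cnvs: list[CNVRecord], model: RandomForestClassifier
    ) -> list[CNVFeatureRow]:
        rows = []
        for cnv in cnvs:
            genes = self.cnv_genes(cnv)
            X = self.vectorize([(g, cnv.phenotypes) for g in genes])
            _, flag = predict_causative(model, X)
            cnv.causative_gene = flag
            if cnv.dgv_frequency is None:
                cnv.dgv_frequency = dgv_frequency(
                    cnv, self.res.dgv, self.cfg.dgv_overlap_threshold
                )
            rows.append(
                CNVFeatureRow(
                    causative_gene=flag,
                    length=cnv.length,
                    dgv=cnv.dgv_frequency,
                    label=cnv.label,
                )
            )
        return rows

    # -- one run -------------------------------------------------------------

    def run_once(self, cnvs: list[CNVRecord], seed: int) -> tuple[EvalMetrics, np.ndarray]:
        split = (
            balanced_split(cnvs, seed)
            if self.cfg.regime == "balanced"
            else unbalanced_split(cnvs, seed)
        )
        items, labels, copies = self.gene_training_rows(split.gene_train)
        if not items:
            raise ValueError("gene training pool produced no gene rows")
        X = self.vectorize(items)
        X_rep = np.repeat(X, copies, axis=0)
        y_rep = np.repeat(np.array(labels, dtype=bool), copies)
        model = train_gene_classifier(X_rep, y_rep, self.cfg, seed)

        train_rows = self.cnv_feature_rows(split.cnv_train, model)
        nb = train_cnv_classifier(train_rows, features=self.cfg.cnv_features)
        test_rows = self.cnv_feature_rows(split.cnv_test, model)
        preds = nb.predict(test_rows)
        metrics = evaluate(preds, [bool(r.label) for r in test_rows])
        return metrics, model.feature_importances_


def run_experiment(
    cnvs: list[CNVRecord], resources: Resources, config: RunConfig
) -> EvalReport:
    """Full protocol: split -> gene model -> causative flags -> CNV model
    -> metrics, repeated over the configured runs and averaged."""
    pipe = Pipeline(resources, config)
    pipe.set_phenotype_vocabulary(cnvs)
    seeds = run_seeds(config)
    runs: list[EvalMetrics] = []
    importances = np.zeros(len(pipe.feature_names))
    for s in seeds:
        metrics, imp = pipe.run_once(cnvs, s)
        logger.info(
            "run seed=%d precision=%.4f recall=%.4f f1=%.4f",
            s, metrics.precision, metrics.recall, metrics.f1,
        )
        runs.append(metrics)
        importances += imp
    importances /= len(seeds)
    return EvalReport(
        runs=runs,
        seeds=seeds,
        feature_importances=dict(zip(pipe.feature_names, importances.tolist())),
    )
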