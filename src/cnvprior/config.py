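"""Run configuration: defaults, validation, YAML round-trip.

Every algorithm parameter lives here with its canonical default: top 5%
of network edges retained, 30-gene Dijkstra subnetworks, 10 closest
neighbors contributing features, restart probability 0.5 for the
ranking walk, 1000 training copies per CNV, a 50% overlap gate for the
benign-region score, and 20 evaluation runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "run_seeds"]

_FEATURE_WEIGHTINGS = ("network-uniform", "network-weighted")
_GENE_WEIGHTINGS = ("phenotype-uniform", "phenotype-weighted")
_REGIMES = ("balanced", "unbalanced")
_CNV_FEATURES = ("gene", "length", "dgv")


@dataclass
class RunConfig:
    # resource paths (optional; in-memory bundles bypass them)
    cnv_table: str | None = None
    gene_models: str | None = None
    go_obo: str | None = None
    hpo_obo: str | None = None
    go_annotations: str | None = None
    hpo_annotations: str | None = None
    slim_terms: str | None = None
    network: str | None = None
    catalog: str | None = None
    dgv_table: str | None = None

    # network / feature parameters
    edge_fraction: float = 0.05
    subnetwork_size: int = 30
    k_neighbors: int = 10
    restart_alpha: float = 0.5
    walk_tol: float = 1e-9
    walk_max_iter: int = 10_000
    feature_weighting: str = "network-weighted"

    # gene weighting
    gene_weighting: str = "phenotype-weighted"
    copies_per_cnv: int = 1000

    # CNV features
    dgv_overlap_threshold: float = 0.5
    cnv_features: tuple[str, ...] = ("gene", "length", "dgv")

    # classifiers
    rf_trees: int = 100
    rf_max_features: str = "sqrt"

    # evaluation protocol
    regime: str = "balanced"
    runs: int = 20
    seed: int | None = None
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.cnv_features = tuple(self.cnv_features)
        if self.seeds is not None:
            self.seeds = tuple(self.seeds)
        self.validate()

    def validate(self) -> None:
        def check(ok: bool, key: str, msg: str) -> None:
            if not ok:
                raise ValueError(f"config key {key!r}: {msg}")

        check(0 < self.edge_fraction <= 1, "edge_fraction", "must be in (0, 1]")
        check(self.subnetwork_size >= 1, "subnetwork_size", "must be >= 1")
        check(self.k_neighbors >= 0, "k_neighbors", "must be >= 0")
        check(0 < self.restart_alpha < 1, "restart_alpha", "must be in (0, 1)")
        check(self.walk_tol > 0, "walk_tol", "must be positive")
        check(self.walk_max_iter >= 1, "walk_max_iter", "must be >= 1")
        check(
            self.feature_weighting in _FEATURE_WEIGHTINGS,
            "feature_weighting", f"must be one of {_FEATURE_WEIGHTINGS}",
        )
        check(
            self.gene_weighting in _GENE_WEIGHTINGS,
            "gene_weighting", f"must be one of {_GENE_WEIGHTINGS}",
        )
        check(self.copies_per_cnv >= 1, "copies_per_cnv", "must be >= 1")
        check(
            0 < self.dgv_overlap_threshold <= 1,
            "dgv_overlap_threshold", "must be in (0, 1]",
        )
        check(len(self.cnv_features) >= 1, "cnv_features", "must not be empty")
        for f in self.cnv_features:
            check(f in _CNV_FEATURES, "cnv_features", f"unknown feature {f!r}")
        check(self.rf_trees >= 1, "rf_trees", "must be >= 1")
        check(self.regime in _REGIMES, "regime", f"must be one of {_REGIMES}")
        check(self.runs >= 1, "runs", "must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnv_features"] = list(self.cnv_features)
        if self.seeds is not None:
            d["seeds"] = list(self.seeds)
        return d


def run_seeds(config: RunConfig) -> list[int]:
    """Per-run seeds: explicit list if given; otherwise run i uses seed i
    (1..runs), offset deterministically when a base seed is set."""
    if config.seeds is not None:
        return list(config.seeds)
    base = 0 if config.seed is None else config.seed * 1000
    return [base + i for i in range(1, config.runs + 1)]


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Merge keyword overrides over a YAML file over the defaults.

    Unknown keys are rejected by name.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**values)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
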