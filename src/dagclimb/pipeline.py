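"""End-to-end pipeline: load -> curate -> standardize -> search -> quantify
-> bootstrap, driven by a single serializable configuration.

One YAML config drives every stage, so a sensitivity analysis (rerun on a
cohort subset or with a different clustering threshold) is one config edit
plus ``compare``.  Each run writes a self-contained directory:

    config.yaml      the effective configuration, echoed verbatim
    graph.json/.dot  the learned DAG
    effects.tsv      edge coefficients and total-effect decomposition
    pathways.txt     every directed path into the outcome
    factors.json     aggregation membership/loadings (when aggregation ran)
    edges_boot.tsv   bootstrap edge-stability table (when bootstrap ran)
    run.log          stage-by-stage log (rows dropped, moves accepted, ...)
    MANIFEST.json    artifact list with SHA-256 content hashes
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .aggregation import aggregated_dataset, cluster_and_aggregate
from .dag import ConfigError, build_constraints, enumerate_pathways
from .effects import effect_report, fit_path_model
from .scoring import standardize, StandardizedDataset
from .search import DEFAULT_TOLERANCE, hill_climb
from .stability import bootstrap_dag

__all__ = ["RunConfig", "run_pipeline", "load_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    data: str                       # path to CSV/TSV with header row
    outcome: str
    delimiter: str = ","
    exogenous_score: list[str] = field(default_factory=list)
    protected_targets: list[str] = field(default_factory=list)  # default: all predictors
    aggregate: bool = False
    aggregate_vars: list[str] = field(default_factory=list)
    r_threshold: float = 0.7
    linkage_method: str = "average"
    tolerance: float = DEFAULT_TOLERANCE
    max_iter: int | None = None
    max_in_degree: int | None = None
    bootstrap: bool = False
    bootstrap_B: int = 100
    bootstrap_seed: int = 0
    bootstrap_min_freq: float = 0.40
    bootstrap_mode: str = "fixed"   # "fixed" | "full" (refit aggregation per replicate)
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "data" not in obj or "outcome" not in obj:
            raise ConfigError("config must set 'data' and 'outcome'")
        return cls(**obj)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def load_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a numeric table and apply listwise deletion (logged)."""
    table = pd.read_csv(path, sep=delimiter)
    n0 = len(table)
    table = table.dropna()
    dropped = n0 - len(table)
    if dropped:
        logger.info("listwise deletion removed %d of %d rows", dropped, n0)
    return table.reset_index(drop=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full flow; returns the run directory.

    Any stage failure raises with the stage named; artifacts written before
    the failure are retained and MANIFEST.json marks the run incomplete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dagclimb")
    root.addHandler(handler)
    prev_level = root.level
    root.setLevel(logging.INFO)
    artifacts: list[Path] = [log_path]
    stage = "config"
    try:
        cfg.to_yaml(out / "config.yaml")
        artifacts.append(out / "config.yaml")

        stage = "load"
        raw = load_table(cfg.data, cfg.delimiter)
        if cfg.outcome not in raw.columns:
            raise ConfigError(f"outcome {cfg.outcome!r} not a column of {cfg.data}")

        stage = "aggregate"
        factor_names: list[str] = []
        if cfg.aggregate:
            agg_vars = cfg.aggregate_vars or [
                c for c in raw.columns
                if c != cfg.outcome and c not in cfg.exogenous_score
            ]
            base = standardize(raw)
            factors = cluster_and_aggregate(
                base, agg_vars, cfg.r_threshold, linkage_method=cfg.linkage_method
            )
            passthrough = [c for c in raw.columns if c not in agg_vars]
            data = aggregated_dataset(base, factors, passthrough)
            factor_names = [f.name for f in factors]
            with open(out / "factors.json", "w", encoding="utf-8") as fh:
                json.dump(
                    [
                        {"name": f.name, "members": f.members,
                         "loadings": [float(l) for l in f.loadings],
                         "variance_explained": float(f.variance_explained)}
                        for f in factors
                    ],
                    fh, indent=2,
                )
            artifacts.append(out / "factors.json")
            logger.info("aggregation: %d variables -> %d factors", len(agg_vars), len(factors))
        else:
            stage = "standardize"
            data = standardize(raw)

        stage = "constraints"
        protected = cfg.protected_targets or [
            c for c in data.columns if c != cfg.outcome and c not in cfg.exogenous_score
        ]
        constraints = build_constraints(
            data.columns,
            outcome_vars=[cfg.outcome],
            exogenous_score_vars=cfg.exogenous_score,
            protected_targets=protected,
        )

        stage = "search"
        result = hill_climb(
            data, constraints, tolerance=cfg.tolerance,
            max_iter=cfg.max_iter, max_in_degree=cfg.max_in_degree,
        )
        logger.info("search: %d iterations, score %.4f, %d edges",
                    result.iterations, result.score, len(result.graph.edges))
        for move, delta in result.trace:
            logger.info("accepted %s %s (delta %.6f)", move.kind, move.edge, delta)
        result.graph.to_json(out / "graph.json")
        result.graph.to_dot(out / "graph.dot")
        artifacts += [out / "graph.json", out / "graph.dot"]

        stage = "effects"
        model = fit_path_model(data, result.graph)
        report = effect_report(model, cfg.outcome)
        report.to_csv(out / "effects.tsv", sep="\t", index=False)
        artifacts.append(out / "effects.tsv")

        stage = "pathways"
        paths = enumerate_pathways(result.graph, cfg.outcome)
        with open(out / "pathways.txt", "w", encoding="utf-8") as fh:
            for p in paths:
                fh.write(" -> ".join(p) + "\n")
        artifacts.append(out / "pathways.txt")

        if cfg.bootstrap:
            stage = "bootstrap"
            if cfg.bootstrap_mode == "full" and cfg.aggregate:
                agg_vars_b = agg_vars

                def prepare(vals, names):
                    frame = pd.DataFrame(vals, columns=names)
                    base_b = standardize(frame)
                    fs = cluster_and_aggregate(
                        base_b, agg_vars_b, cfg.r_threshold, linkage_method=cfg.linkage_method
                    )
                    pt = [c for c in names if c not in agg_vars_b]
                    return aggregated_dataset(base_b, fs, pt)

                boot_input: StandardizedDataset | pd.DataFrame = raw
                boot = bootstrap_dag(
                    boot_input, constraints, B=cfg.bootstrap_B, seed=cfg.bootstrap_seed,
                    min_freq=cfg.bootstrap_min_freq, prepare=prepare,
                    search_kwargs={"tolerance": cfg.tolerance, "max_iter": cfg.max_iter,
                                   "max_in_degree": cfg.max_in_degree},
                )
            else:
                boot = bootstrap_dag(
                    data, constraints, B=cfg.bootstrap_B, seed=cfg.bootstrap_seed,
                    min_freq=cfg.bootstrap_min_freq,
                    search_kwargs={"tolerance": cfg.tolerance, "max_iter": cfg.max_iter,
                                   "max_in_degree": cfg.max_in_degree},
                )
            boot.to_frame().to_csv(out / "edges_boot.tsv", sep="\t", index=False)
            artifacts.append(out / "edges_boot.tsv")
            logger.info("bootstrap: %d replicates (%d failed), %d edges reported",
                        boot.B, boot.n_failed, len(boot.stats))

        stage = "manifest"
        _write_manifest(out, artifacts, complete=True)
        return out
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        _write_manifest(out, [a for a in artifacts if a.exists()], complete=False, failed_stage=stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        handler.close()
        root.removeHandler(handler)
        root.setLevel(prev_level)


def _write_manifest(out: Path, artifacts: list[Path], complete: bool, failed_stage: str | None = None):
    manifest = {
        "complete": complete,
        "failed_stage": failed_stage,
        "artifacts": {a.name: _sha256(a) for a in sorted(set(artifacts)) if a.exists()},
    }
    with open(out / "MANIFEST.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
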