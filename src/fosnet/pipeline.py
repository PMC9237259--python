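"""One-config orchestration: cohort -> stats -> networks -> hubs -> ML.

``run_pipeline`` executes the full analysis from a single
:class:`PipelineConfig` and writes a report bundle: per-group ANOVA tables,
correlation matrices, thresholded whole-brain graphs, hub reports, the
motor-circuit subnetwork, the seed-region (M1) ego network, an optional
behavior-prediction report, and a MANIFEST with a sha256 checksum per file,
the config hash, and the seed. Re-running the same config reproduces the
same checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import DEFAULT_GROUPS, CohortMatrix, ValidationError
from .io import read_cohort, write_cohort, write_network
from .ml import ALGORITHMS, FeatureSpec, fit_predictors, normalize_rmse, rank_models
from .network import (
    ego_network,
    identify_hubs,
    interregional_correlation,
    motor_subnetwork,
    threshold_network,
)
from .stats import anova_table_by_region, tukey_hsd
from .synthetic import generate_cohort, make_recovery_scenario

logger = logging.getLogger("fosnet.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summary_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults follow the standard protocol
    (whole-brain threshold 0.6, motor threshold 0.5, degree >= 5,
    betweenness top 10)."""

    cohort_path: str | None = None
    scenario: str | None = None
    n_per_group: int = 6
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    method: str = "pearson"
    tau_whole: float = 0.6
    tau_motor: float = 0.5
    degree_min: int = 5
    betweenness_top_k: int = 10
    ego_center: str = "M1"
    ml_target: str | None = None
    ml_features: list[str] | None = None
    outdir: str = "fosnet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, tau in (("tau_whole", self.tau_whole),
                          ("tau_motor", self.tau_motor)):
            if not 0.0 < tau < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {tau}")
        if (self.cohort_path is None) == (self.scenario is None):
            raise ValidationError(
                "configure exactly one input: cohort_path or scenario"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is excluded: the same analysis in two directories is the
        # same analysis
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input(config: PipelineConfig) -> CohortMatrix:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path, groups=config.groups)
    summary, specs = make_recovery_scenario(config.scenario)
    return generate_cohort(summary, n_per_group=config.n_per_group,
                           corr_specs=specs, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the bundle dir.

    On stage failure a :class:`PipelineError` naming the stage is raised;
    artifacts written so far are kept and the MANIFEST records the bundle as
    incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {},
        "complete": False,
    }
    files: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        files[name] = path

    stage = "load_input"
    try:
        cohort = _load_input(config)
        sizes = cohort.group_sizes()
        logger.info("loaded cohort: %d animals, %d regions, groups %s",
                    cohort.n_animals, len(cohort.regions), sizes)
        path = outdir / "cohort.csv"
        write_cohort(cohort, path)
        record("cohort", path)

        stage = "group_stats"
        anova = anova_table_by_region(cohort)
        path = outdir / "anova_by_region.csv"
        anova.to_csv(path)
        record("anova_by_region", path)
        tukey_rows = []
        for region in cohort.regions:
            by_group = {
                g: cohort.data.loc[cohort.data["group"] == g, region].to_numpy()
                for g in cohort.groups if sizes.get(g, 0) >= 2
            }
            for cmp_ in tukey_hsd(by_group):
                tukey_rows.append({"region": region, "group_a": cmp_.group_a,
                                   "group_b": cmp_.group_b,
                                   "mean_diff": cmp_.mean_diff,
                                   "p_adj": cmp_.p_adj})
        path = outdir / "tukey_by_region.csv"
        pd.DataFrame(tukey_rows).to_csv(path, index=False)
        record("tukey_by_region", path)

        stage = "networks"
        per_group_edges: dict[str, dict] = {}
        for g in cohort.groups:
            if sizes.get(g, 0) < 3:
                logger.info("skipping group %s (fewer than 3 animals)", g)
                continue
            net = interregional_correlation(cohort, g, method=config.method)
            path = outdir / f"correlation_{g}.csv"
            net.weights.to_csv(path)
            record(f"correlation_{g}", path)

            graph = threshold_network(net, tau=config.tau_whole)
            path = outdir / f"graph_{g}.graphml"
            write_network(graph, path, format="graphml")
            record(f"graph_{g}", path)

            hubs = identify_hubs(graph, degree_min=config.degree_min,
                                 betweenness_top_k=config.betweenness_top_k)
            path = outdir / f"hubs_{g}.csv"
            hubs.to_csv(path)
            record(f"hubs_{g}", path)

            motor = motor_subnetwork(net, tau=config.tau_motor)
            path = outdir / f"motor_{g}.tsv"
            write_network(motor, path, format="tsv")
            record(f"motor_{g}", path)

            ego = ego_network(graph, center=config.ego_center)
            path = outdir / f"ego_{config.ego_center}_{g}.graphml"
            write_network(ego, path, format="graphml")
            record(f"ego_{g}", path)

            per_group_edges[g] = {
                "whole_edges": graph.n_edges,
                "motor_edges": motor.n_edges,
                "hubs": sorted(hubs.index[hubs["hub"]]),
            }
            logger.info("group %s: %d whole-brain edges, %d motor edges, "
                        "%d hubs", g, graph.n_edges, motor.n_edges,
                        len(per_group_edges[g]["hubs"]))

        stage = "behavior_ml"
        ml_summary = None
        if config.ml_target and config.ml_target in cohort.data.columns:
            spec = FeatureSpec(
                features=(config.ml_features
                          or [f for f in cohort.regions + cohort.behavior_columns
                              if f != config.ml_target][:10]),
                target=config.ml_target,
            )
            report = fit_predictors(cohort, spec, seed=config.seed)
            ml_summary = {
                "ranking": rank_models(report),
                "rmse_l1": normalize_rmse(
                    {m: f.rmse for m, f in report.models.items()}
                ),
                "metrics": report.metrics_frame().to_dict(orient="index"),
            }
            path = outdir / "ml_metrics.csv"
            report.metrics_frame().to_csv(path)
            record("ml_metrics", path)
            path = outdir / "ml_importances.csv"
            report.importance_frame().to_csv(path, index=False)
            record("ml_importances", path)

        stage = "summary"
        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "group_sizes": sizes,
            "per_group": per_group_edges,
            "ml": ml_summary,
        }
        path = outdir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        record("summary", path)
        manifest["complete"] = True
    except Exception as exc:  # keep partial outputs, then re-raise
        manifest["failed_stage"] = stage
        manifest["files"] = {k: _sha256(v) for k, v in files.items()}
        (outdir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    manifest["files"] = {k: _sha256(v) for k, v in files.items()}
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return outdir


def summary_report(bundle: str | Path) -> str:
    """Human-readable digest of a bundle; every number is read from files."""
    bundle = Path(bundle)
    summary_path = bundle / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"bundle {bundle} has no summary.json (incomplete run?)"
        )
    summary = json.loads(summary_path.read_text())
    lines = [
        f"fosnet report (seed {summary['seed']}, "
        f"config {summary['config_hash']})",
        "",
    ]
    for g, info in (summary.get("per_group") or {}).items():
        hubs = info["hubs"]
        lines.append(
            f"  {g}: {info['whole_edges']} whole-brain edges, "
            f"{info['motor_edges']} motor-circuit edges, "
            f"{len(hubs)} hub(s){': ' + ', '.join(hubs) if hubs else ''}"
        )
    ml = summary.get("ml")
    if ml:
        lines.append("")
        lines.append("  model ranking: " + " > ".join(ml["ranking"]))
    return "\n".join(lines)
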