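"""End-to-end orchestration: config, stages, and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from . import descriptors as desc
from . import network as net
from . import regression as reg
from . import stats as st
from .growth import SimConfig, summarize_replicates
from .io import read_concentration_table, read_feature_table, write_predictions

logger = logging.getLogger("chemtopo")

__all__ = ["PipelineConfig", "ConfigError", "PipelineStageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; round-trips losslessly through
    YAML/JSON and rejects unknown keys."""

    reactions: str | None = None
    annotations: str | None = None
    smiles: str | None = None
    concentrations: str | None = None
    features: str | None = None
    group_scheme: list = field(
        default_factory=lambda: [["degree 1", 1, 1], ["degree 2-6", 2, 6], ["degree >6", 7, None]]
    )
    stepwise: dict = field(default_factory=lambda: {"p_enter": 0.05, "p_remove": 0.10})
    svr: dict = field(default_factory=lambda: {"gamma": 0.01, "epsilon": 0.22, "cost": 7.9})
    simulator: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "chemtopo_out"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def scheme(self) -> st.GroupScheme:
        return st.GroupScheme.from_edges(
            [(label, int(lo), None if hi is None else int(hi)) for label, lo, hi in self.group_scheme]
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write a manifest.

    Stages: reconstruct (reaction list -> network, degrees, power-law fit),
    descriptors (SMILES -> panel), correlate (degree-binned summaries and
    trend), models (stepwise MLR + SVR LOOCV when concentrations are given),
    simulate (when simulator parameters are configured). A stage failure
    aborts the run with the stage name; outputs written so far are listed in
    the raised error's manifest as stale.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for key in ("reactions", "annotations", "smiles", "concentrations", "features"):
        path = getattr(config, key)
        if path is not None:
            if not Path(path).exists():
                raise ConfigError(f"input {key!r} not found: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    degrees_df: pd.DataFrame | None = None
    panel_df: pd.DataFrame | None = None

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    # --- reconstruct -------------------------------------------------------
    if config.reactions is not None:
        stage = "reconstruct"
        try:
            reactions = net.parse_reactions(config.reactions)
            if config.annotations is None:
                raise ConfigError("reconstruct needs an annotation table")
            annotations = net.read_annotations(config.annotations)
            filtered = net.filter_reactions(reactions, annotations)
            graph = net.build_network(filtered)
            degrees_df = net.compute_degrees(graph)
            net.write_edge_list(graph, out / "edges.tsv")
            record(stage, "edges", out / "edges.tsv")
            nx.write_graphml(graph, out / "network.graphml")
            record(stage, "graphml", out / "network.graphml")
            net.write_degree_table(degrees_df, out / "degrees.tsv")
            record(stage, "degrees", out / "degrees.tsv")
            if not degrees_df.empty:
                hist = net.degree_histogram(degrees_df)
                if len(hist) >= 3:
                    net.write_powerlaw_json(net.fit_power_law(hist), out / "powerlaw.json")
                    record(stage, "powerlaw", out / "powerlaw.json")
            logger.info("reconstruct: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())
        except ConfigError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # --- descriptors -------------------------------------------------------
    if config.smiles is not None:
        stage = "descriptors"
        try:
            table = desc.read_smiles_table(config.smiles)
            panels, failures = desc.build_panel(table)
            desc.write_panel_table(panels, out / "panel.tsv")
            record(stage, "panel", out / "panel.tsv")
            (out / "descriptor_failures.json").write_text(json.dumps(failures, indent=2))
            record(stage, "descriptor_failures", out / "descriptor_failures.json")
            panel_df = desc.panels_to_frame(panels).set_index("id")
            logger.info("descriptors: %d panels, %d failures", len(panels), len(failures))
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # --- correlate ---------------------------------------------------------
    if degrees_df is not None and panel_df is not None and not degrees_df.empty:
        stage = "correlate"
        try:
            scheme = config.scheme()
            summary = st.summary_table(degrees_df, panel_df.reset_index(), scheme)
            summary.to_csv(out / "summary.tsv", sep="\t", index=False)
            record(stage, "summary", out / "summary.tsv")
            report = {}
            deg_map = dict(zip(degrees_df["id"], degrees_df["degree"]))
            for col in panel_df.columns:
                sums = st.group_by_degree(deg_map, panel_df[col], scheme)
                if sum(1 for s in sums if not s.empty) >= 3:
                    r, p = st.binned_correlation(sums)
                    report[col] = {"R": r, "p": p}
            (out / "correlation.json").write_text(json.dumps(report, indent=2))
            record(stage, "correlation", out / "correlation.json")
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # --- models ------------------------------------------------------------
    if config.concentrations is not None:
        stage = "models"
        try:
            records = read_concentration_table(config.concentrations)
            y = pd.Series({r.id: r.neg_log_c for r in records})
            if config.features is not None:
                X = read_feature_table(config.features)
            elif panel_df is not None:
                X = panel_df.drop(columns=["logs"], errors="ignore")
                if degrees_df is not None:
                    X = X.join(degrees_df.set_index("id")["degree"], how="left")
            else:
                raise ConfigError("models need a feature table or a descriptors stage")
            common = [i for i in y.index if i in X.index]
            X = X.loc[common].dropna(axis=1)
            yv = y.loc[common].to_numpy()

            sw = reg.StepwiseLinearRegression(**config.stepwise).fit(X, yv)
            (out / "mlr_model.json").write_text(sw.model_.to_json())
            record(stage, "mlr_model", out / "mlr_model.json")
            write_predictions(common, sw.predict(X), out / "mlr_predictions.tsv")
            record(stage, "mlr_predictions", out / "mlr_predictions.tsv")

            svr = reg.ConcentrationSVR(**config.svr)
            report = reg.loocv(svr, X, yv)
            (out / "svr_loocv.json").write_text(
                json.dumps(
                    {
                        "gamma": config.svr["gamma"],
                        "epsilon": config.svr["epsilon"],
                        "cost": config.svr["cost"],
                        "squared_correlation": report.squared_correlation,
                        "total_mse": report.total_mse,
                        "no_intercept_slope": reg.no_intercept_slope(
                            report.predictions, report.observed
                        ),
                    },
                    indent=2,
                )
            )
            record(stage, "svr_loocv", out / "svr_loocv.json")
        except ConfigError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # --- simulate ----------------------------------------------------------
    if config.simulator:
        stage = "simulate"
        try:
            params = dict(config.simulator)
            seeds = params.pop("seeds", [config.seed])
            if isinstance(seeds, int):
                seeds = list(range(config.seed, config.seed + seeds))
            sim_cfg = SimConfig(seed=config.seed, **params)
            table, results = summarize_replicates(sim_cfg, seeds)
            table.to_csv(out / "simulation_runs.tsv", sep="\t", index=False)
            record(stage, "simulation_runs", out / "simulation_runs.tsv")
            footer = {
                "mean_n_nodes": float(table["n_nodes"].mean()),
                "sd_n_nodes": float(table["n_nodes"].std(ddof=1)) if len(table) > 1 else 0.0,
                "mean_b": float(table["b"].mean()),
                "mean_r_squared": float(table["r_squared"].mean()),
            }
            (out / "simulation_summary.json").write_text(json.dumps(footer, indent=2))
            record(stage, "simulation_summary", out / "simulation_summary.json")
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
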