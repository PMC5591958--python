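"""End-to-end orchestration: simulate -> filter -> associate -> network ->
topology -> enrich -> qpcr, with a reproducibility manifest.

Every stage writes its artifacts as new files (inputs are never mutated)
and records parameters plus SHA-256 checksums in ``manifest.json``; an
identical config and seed reproduces identical manifest checksums.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, enrich, ggm, preprocess, qpcr, synthdata, topology
from .ioformats import (
    checksum,
    read_bed,
    read_expression,
    read_samples,
    write_network,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds for a full run.

    Thresholds default to the headline operating point: 5% detection
    fraction, Spearman alpha 0.05, posterior edge probability 0.95.
    """

    outdir: str = "emp_mirnet_run"
    expression: str | None = None
    detection: str | None = None
    samples: str | None = None
    loci: str | None = None
    ct_table: str | None = None
    simulate: bool = True
    synthetic: synthdata.SyntheticConfig = field(default_factory=synthdata.SyntheticConfig)
    min_detect_fraction: float = 0.05
    alpha: float = 0.05
    use_fdr: bool = False
    prob_threshold: float = 0.95
    fit_method: str = "empirical"
    node_policy: str = "edge-incident"
    universe_policy: str = "platform"  # or "expressed"
    reference_group: str = "TAV"
    run_qpcr: bool = True
    qpcr_n_targets: int = 6
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_detect_fraction", "alpha", "prob_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError("config", f"{name} must lie in (0, 1), got {v}")
        if self.universe_policy not in ("platform", "expressed"):
            raise PipelineError("config", f"unknown universe_policy {self.universe_policy!r}")
        if not self.simulate:
            for name in ("expression", "samples", "loci"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineError("config", f"{name} input required when simulate=False")
                if not os.path.exists(path):
                    raise PipelineError("config", f"{name} file not found: {path}")

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth_raw = raw.pop("synthetic", {})
        for key in ("partial_cor_range", "assoc_strength_range", "group_labels"):
            if key in synth_raw:
                synth_raw[key] = tuple(synth_raw[key])
        cfg = cls(**{k: v for k, v in raw.items() if k != "synthetic"})
        cfg.synthetic = synthdata.SyntheticConfig(**synth_raw)
        return cfg


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(config: PipelineConfig, log=None) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    say = log if log is not None else (lambda msg: None)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _to_jsonable(config),
        "stages": {},
        "checksums": {},
    }
    art: dict[str, str] = {}

    def record(stage: str, outputs: dict[str, str], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: os.path.basename(v) for k, v in outputs.items()},
            **_to_jsonable(info),
        }
        for key, path in outputs.items():
            manifest["checksums"][os.path.basename(path)] = checksum(path)
        art.update(outputs)

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    # --- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            synth_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
            paths = synthdata.write_dataset(out("synthetic"), synth_cfg)
            expr = read_expression(paths["expression"], paths["detection"])
            samples = read_samples(paths["samples"])
            loci = read_bed(paths["loci"])
            truth = synthdata.read_truth(paths["truth"])
            record(stage, paths, n_features=expr.n_features, n_samples=expr.n_samples)
            say(f"simulate: {expr.n_features} features x {expr.n_samples} samples")
        else:
            expr = read_expression(config.expression, config.detection)
            samples = read_samples(config.samples)
            loci = read_bed(config.loci)
            truth = None
            say(f"load: {expr.n_features} features x {expr.n_samples} samples")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- filter ------------------------------------------------------------
    stage = "filter"
    try:
        samples = preprocess.log_transform_emp(samples)
        expr_f, report = preprocess.filter_expressed(expr, config.min_detect_fraction)
        path = out("filter_report.tsv")
        pd.DataFrame({"feature_id": report.kept_ids}).to_csv(path, sep="\t", index=False)
        anova = preprocess.compare_emp_groups(samples)
        anova_path = out("emp_groups.tsv")
        anova["tukey"].assign(F=anova["F"], p_anova=anova["p"]).to_csv(
            anova_path, sep="\t", index=False
        )
        record(stage, {"filter_report": path, "emp_groups": anova_path},
               n_input=report.n_input, n_expressed=report.n_expressed)
        say(f"filter: {report.n_expressed}/{report.n_input} features expressed")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- associate ----------------------------------------------------------
    stage = "associate"
    try:
        table = assoc.screen(expr_f, samples, alpha=config.alpha, use_fdr=config.use_fdr)
        path = out("association.tsv")
        table.to_csv(path, sep="\t", index=False)
        selected = table.loc[table["selected"], "feature_id"].tolist()
        if not selected:
            raise ValueError("no feature passed the association screen")
        record(stage, {"association": path}, n_selected=len(selected))
        say(f"associate: {len(selected)} features at alpha={config.alpha}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- network -------------------------------------------------------------
    stage = "network"
    try:
        expr_sel = expr_f.subset(selected)
        shrink = ggm.shrink_correlation(expr_sel.values.T)
        pcor = ggm.partial_correlations(shrink.r_shrunk)
        offdiag = pcor[np.triu_indices(len(selected), 1)]
        fit = ggm.fit_mixture(offdiag, method=config.fit_method)
        network = ggm.build_network(
            pcor, fit, selected,
            prob_threshold=config.prob_threshold, node_policy=config.node_policy,
        )
        rho_by_id = dict(zip(table["feature_id"], table["rho"]))
        region_by_id = dict(zip(loci["feature_id"], loci["region"]))
        for node in network.graph.nodes():
            network.graph.nodes[node]["spearman_rho"] = float(rho_by_id.get(node, np.nan))
            network.graph.nodes[node]["region"] = str(region_by_id.get(node, ""))
            network.graph.nodes[node]["degree"] = int(network.graph.degree(node))
        edge_path = out("edges.tsv")
        network.edge_table().to_csv(edge_path, sep="\t", index=False)
        graphml_path = out("network.graphml")
        write_network(network.graph, graphml_path, "graphml")
        sif_path = out("network.sif")
        write_network(network.graph, sif_path, "sif")
        fit_path = out("ggm_fit.json")
        with open(fit_path, "w") as fh:
            json.dump(
                {
                    "lambda_star": shrink.lambda_star,
                    "eta0": fit.eta0,
                    "kappa": fit.kappa,
                    "loglik": fit.loglik,
                    "method": fit.method,
                    "n_edges": network.graph.number_of_edges(),
                    "n_nodes": network.graph.number_of_nodes(),
                    "largest_component": sorted(network.largest_component),
                },
                fh, indent=1, sort_keys=True,
            )
        record(
            stage,
            {"edges": edge_path, "graphml": graphml_path, "sif": sif_path, "fit": fit_path},
            n_nodes=network.graph.number_of_nodes(),
            n_edges=network.graph.number_of_edges(),
            lambda_star=shrink.lambda_star,
        )
        say(
            f"network: {network.graph.number_of_nodes()} nodes, "
            f"{network.graph.number_of_edges()} edges "
            f"(largest component {len(network.largest_component)})"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- topology -------------------------------------------------------------
    stage = "topology"
    try:
        report = topology.centralities(network.graph)
        hubs = topology.rank_hubs(report) if len(report) else report
        path = out("topology.tsv")
        hubs.to_csv(path, sep="\t", index=False)
        # the reported hub is the top hub of the largest component (the
        # reported network); per-component rank sums are not comparable
        top_hub = None
        if len(hubs):
            in_largest = hubs["node"].isin(network.largest_component)
            flagged = hubs[in_largest & hubs["is_top_hub"]]
            if len(flagged):
                top_hub = flagged.iloc[0]["node"]
        record(stage, {"topology": path}, top_hub=top_hub)
        say(f"topology: top hub {top_hub}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- enrich -----------------------------------------------------------------
    stage = "enrich"
    try:
        universe = (
            list(loci["feature_id"])
            if config.universe_policy == "platform"
            else [f for f in expr_f.feature_ids if f in set(loci["feature_id"])]
        )
        nodes = sorted(network.largest_component)
        result = enrich.positional_enrichment(nodes, loci, universe)
        path = out("enrichment.tsv")
        result.to_csv(path, sep="\t", index=False)
        top_region = result.iloc[0]["region_or_set"] if len(result) else None
        record(stage, {"enrichment": path}, top_region=top_region,
               universe_size=len(universe), network_size=len(nodes))
        say(f"enrich: top region {top_region}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- qpcr ---------------------------------------------------------------------
    if config.run_qpcr:
        stage = "qpcr"
        try:
            if config.ct_table is not None:
                ct = qpcr.read_ct(config.ct_table)
            elif config.simulate:
                targets = nodes[: config.qpcr_n_targets] or selected[: config.qpcr_n_targets]
                ct = synthdata.sample_ct_table(expr, samples, targets, seed=config.seed)
            else:
                ct = None
            if ct is not None:
                fc = qpcr.fold_change(ct, reference_group=config.reference_group)
                fc_path = out("fold_changes.tsv")
                fc.to_csv(fc_path, sep="\t", index=False)
                val = qpcr.validate_correlations(fc, samples)
                val_path = out("qpcr_validation.tsv")
                val.to_csv(val_path, sep="\t", index=False)
                record(stage, {"fold_changes": fc_path, "validation": val_path},
                       n_targets=val.shape[0])
                say(f"qpcr: {val.shape[0]} targets validated")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest_path = out("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    if truth is not None:
        manifest["_truth"] = truth  # in-memory only, for callers that score recovery
    manifest["_paths"] = {**art, "manifest": manifest_path}
    return manifest
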