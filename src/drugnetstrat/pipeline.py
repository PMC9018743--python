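"""Configuration-driven end-to-end runs.

Stage order is fixed: cohort → terminals → condition interactome → PCSF grid
→ separation matrix → pathway enrichment → drug-level evaluation. Conditions
whose omics yield no usable terminal set are skipped and reported in the run
manifest, mirroring screens where some drugs produce seed lists too small
for network modeling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .cohort import CohortBundle, CohortConfig, generate_cohort
from .compare import SeparationMatrix, separation_matrix
from .enrichment import GeneSetCollection, enrich
from .evaluate import (
    RegressionResult,
    SweepResult,
    predict_combinations,
    sensitivity_association,
    sweep_thresholds,
)
from .interactome import prepare_condition_interactome
from .pcsf import PCSFParams, ReconstructedNetwork, default_grid, grid_reconstruct
from .terminals import (
    InfeasibleCondition,
    TerminalSet,
    assemble_terminal_set,
    differential_expression,
    select_phospho_terminals,
    select_tf_terminals,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "build_condition_terminals",
    "reconstruct_condition",
]

log = logging.getLogger(__name__)

_DEFAULT_THRESHOLDS = tuple(np.round(np.arange(-2.0, 2.0001, 0.05), 10))


@dataclass
class PipelineConfig:
    """All knobs for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None  # load a written cohort instead of generating
    out_dir: str = "run_output"
    alpha_expression: float = 0.05
    alpha_phospho: float = 0.05
    min_tf_targets: int = 3
    expr_threshold: float = 2.0
    hub_degree_threshold: int = 900
    hub_sd_mult: float = 10.0
    grid: list[PCSFParams] = field(default_factory=default_grid)
    moa_thresholds: Sequence[float] = _DEFAULT_THRESHOLDS
    ss_floor: float = -0.45

    def __post_init__(self) -> None:
        if not 0 < self.alpha_expression < 1 or not 0 < self.alpha_phospho < 1:
            raise ValueError("alpha levels must be in (0,1)")
        if self.expr_threshold < 0 or self.min_tf_targets < 1:
            raise ValueError("invalid filter thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            if "baseline_range" in raw["cohort"]:
                raw["cohort"]["baseline_range"] = tuple(raw["cohort"]["baseline_range"])
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "grid" in raw:
            raw["grid"] = [PCSFParams(**g) for g in raw["grid"]]
        return cls(**raw)


@dataclass
class PipelineResult:
    networks: dict[str, ReconstructedNetwork]
    terminals: dict[str, TerminalSet]
    matrix: SeparationMatrix
    enrichments: dict[str, list]
    sweep: SweepResult
    combinations: list
    regression: RegressionResult | None
    dropped: dict[str, str]
    manifest: dict


def build_condition_terminals(
    bundle: CohortBundle,
    cell_line: str,
    drug: str,
    *,
    alpha_expression: float = 0.05,
    alpha_phospho: float = 0.05,
    min_tf_targets: int = 3,
) -> TerminalSet:
    """Omics → prized terminal set for one condition (may raise
    :class:`InfeasibleCondition`)."""
    panel = bundle.panels[(cell_line, drug)]
    diff = differential_expression(panel, alpha=alpha_expression)
    tf_part = select_tf_terminals(diff, bundle.regnet, min_targets=min_tf_targets)
    phospho_part = select_phospho_terminals(
        bundle.phospho_tables[(cell_line, drug)], alpha=alpha_phospho
    )
    return assemble_terminal_set(
        tf_part,
        phospho_part,
        bundle.drug_targets.get(drug, set()),
        condition=bundle.condition_id(cell_line, drug),
    )


def reconstruct_condition(
    bundle: CohortBundle,
    cell_line: str,
    drug: str,
    cfg: PipelineConfig | None = None,
) -> ReconstructedNetwork:
    """Terminals + refined interactome + PCSF grid for one condition."""
    cfg = cfg or PipelineConfig(cohort=bundle.config)
    terminals = build_condition_terminals(
        bundle, cell_line, drug,
        alpha_expression=cfg.alpha_expression,
        alpha_phospho=cfg.alpha_phospho,
        min_tf_targets=cfg.min_tf_targets,
    )
    panel = bundle.panels[(cell_line, drug)]
    expr = dict(zip(panel.genes, panel.treated.mean(axis=1)))
    g_cond = prepare_condition_interactome(
        bundle.interactome, expr, bundle.localization,
        deg_thresh=cfg.hub_degree_threshold,
        sd_mult=cfg.hub_sd_mult,
        expr_thresh=cfg.expr_threshold,
    )
    return grid_reconstruct(
        g_cond, terminals, cfg.grid,
        condition=bundle.condition_id(cell_line, drug),
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages; write per-condition artifacts and a run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = (
        dio.read_cohort(cfg.cohort_dir) if cfg.cohort_dir else generate_cohort(cfg.cohort)
    )

    networks: dict[str, ReconstructedNetwork] = {}
    terminal_sets: dict[str, TerminalSet] = {}
    dropped: dict[str, str] = {}
    meta_rows = []
    for cl, drug in bundle.conditions:
        cond = bundle.condition_id(cl, drug)
        try:
            terminals = build_condition_terminals(
                bundle, cl, drug,
                alpha_expression=cfg.alpha_expression,
                alpha_phospho=cfg.alpha_phospho,
                min_tf_targets=cfg.min_tf_targets,
            )
        except InfeasibleCondition as exc:
            log.info("condition %s dropped: %s", cond, exc)
            dropped[cond] = str(exc)
            continue
        try:
            panel = bundle.panels[(cl, drug)]
            expr = dict(zip(panel.genes, panel.treated.mean(axis=1)))
            g_cond = prepare_condition_interactome(
                bundle.interactome, expr, bundle.localization,
                deg_thresh=cfg.hub_degree_threshold,
                sd_mult=cfg.hub_sd_mult,
                expr_thresh=cfg.expr_threshold,
            )
            net = grid_reconstruct(g_cond, terminals, cfg.grid, condition=cond)
        except InfeasibleCondition as exc:
            dropped[cond] = f"reconstruction infeasible: {exc}"
            continue
        except Exception as exc:
            raise RuntimeError(f"stage 'reconstruction' failed for {cond}: {exc}") from exc
        terminal_sets[cond] = terminals
        networks[cond] = net
        meta_rows.append(
            {"condition": cond, "cell_line": cl, "drug": drug, "moa": bundle.moa_labels[drug]}
        )
        dio.write_network(net, out / f"network_{cond}.tsv")
        dio.write_terminal_set(terminals, out / f"terminals_{cond}.tsv")

    if len(networks) < 2:
        raise RuntimeError("fewer than two feasible conditions; nothing to compare")

    meta = pd.DataFrame(meta_rows).set_index("condition")
    matrix = separation_matrix(
        {c: n.node_set for c, n in networks.items()}, bundle.interactome, meta
    )
    matrix.scores.to_csv(out / "separation_matrix.csv")
    matrix.pairs().to_csv(out / "separation_pairs.tsv", sep="\t", index=False)

    gsc = GeneSetCollection(
        sets=dict(bundle.gene_sets), universe=set(bundle.interactome.nodes())
    )
    enrichments = {c: enrich(n.node_set, gsc) for c, n in networks.items()}

    sweep = sweep_thresholds(matrix, cfg.moa_thresholds)
    sweep.table.to_csv(out / "metrics_by_threshold.csv", index=False)

    combos = predict_combinations(
        {c: n.node_set for c, n in networks.items()},
        enrichments, matrix, bundle.driver_genes,
    )
    pd.DataFrame([c.__dict__ for c in combos]).to_csv(
        out / "combinations.tsv", sep="\t", index=False
    )

    try:
        regression = sensitivity_association(matrix, bundle.sensitivity, ss_floor=cfg.ss_floor)
        (out / "regression.json").write_text(json.dumps(regression.__dict__, indent=1))
    except ValueError as exc:
        log.info("sensitivity regression skipped: %s", exc)
        regression = None

    manifest = _build_manifest(cfg, out, networks, dropped, sweep, regression)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        networks=networks,
        terminals=terminal_sets,
        matrix=matrix,
        enrichments=enrichments,
        sweep=sweep,
        combinations=combos,
        regression=regression,
        dropped=dropped,
        manifest=manifest,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["moa_thresholds"] = [float(t) for t in d["moa_thresholds"]]
    return d


def _build_manifest(cfg, out: Path, networks, dropped, sweep, regression) -> dict:
    file_hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.csv"))
    }
    return {
        "config": _config_dict(cfg),
        "seed": cfg.cohort.seed,
        "n_networks": len(networks),
        "conditions": sorted(networks),
        "dropped": dropped,
        "best_threshold": sweep.best.threshold,
        "best_mcc": sweep.best.mcc,
        "auc": sweep.auc,
        "regression": None if regression is None else regression.__dict__,
        "files": file_hashes,
    }
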