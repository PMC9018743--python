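"""Fully synthetic drug-perturbation study with planted ground truth.

The generator emulates the statistical structure of a CMap-style screen —
replicate fluorescence panels for drug vs vehicle control, phosphoprotein
fold-change tables, a TF→target regulatory network, drug→target maps,
subcellular localization, MoA labels and drug-sensitivity z-scores — on top
of a confidence-weighted scale-free interactome with planted pathway
modules. Every drug perturbs the modules of its MoA class, so drugs sharing
a mechanism truly share perturbed pathway neighborhoods: the downstream
pipeline can be validated against this planted truth without any external
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import REFERENCE
from .terminals import ExpressionPanel

__all__ = ["CohortConfig", "CohortBundle", "generate_interactome", "generate_cohort"]

@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    ``effect_size`` is the expression shift (log2-scale fluorescence units)
    applied to genes of a drug's planted modules; ``noise_sd`` the replicate
    noise SD; ``baseline_range`` the interval of baseline expression, chosen
    to live on the same 0–15 fluorescence scale that makes the absolute
    expression-filter threshold of 2.0 meaningful.
    """

    n_proteins: int = 300
    n_pathway_modules: int = 12
    module_size: int = 15
    n_tfs: int = 24
    n_drugs: int = 8
    n_cell_lines: int = 2
    n_moa_classes: int = 4
    n_replicates: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (0.0, 15.0)
    frac_phospho: float = 0.4
    n_compartments: int = 5
    frac_unlocalized: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_proteins, self.n_pathway_modules, self.module_size,
            self.n_tfs, self.n_drugs, self.n_cell_lines, self.n_moa_classes,
            self.n_replicates, self.n_compartments,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.module_size * self.n_pathway_modules + self.n_tfs > self.n_proteins:
            raise ValueError("modules plus TFs exceed the protein universe")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >=0 and noise_sd > 0")
        for f in (self.frac_phospho, self.frac_unlocalized):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.n_moa_classes > self.n_pathway_modules:
            raise ValueError("need at least one pathway module per MoA class")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per arm")


@dataclass
class CohortBundle:
    """Everything a study needs, with the planted truth attached."""

    config: CohortConfig
    interactome: nx.Graph
    panels: dict[tuple[str, str], ExpressionPanel]
    phospho_tables: dict[tuple[str, str], pd.DataFrame]
    regnet: dict[str, set[str]]
    drug_targets: dict[str, set[str]]
    localization: dict[str, set[str]]
    gene_sets: dict[str, set[str]]
    moa_labels: dict[str, str]
    driver_genes: set[str]
    sensitivity: dict[tuple[str, str], float]
    truth: dict[str, list[str]] = field(default_factory=dict)

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return sorted(self.panels)

    def condition_id(self, cell_line: str, drug: str) -> str:
        return f"{cell_line}_{drug}"


def _layout(config: CohortConfig) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Deterministic partition of the protein universe into TFs and modules."""
    names = [f"P{i:04d}" for i in range(config.n_proteins)]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    shuffled = [str(x) for x in rng.permutation(names)]
    tfs = sorted(shuffled[: config.n_tfs])
    modules: dict[str, list[str]] = {}
    offset = config.n_tfs
    for m in range(config.n_pathway_modules):
        members = shuffled[offset + m * config.module_size : offset + (m + 1) * config.module_size]
        modules[f"module_{m:02d}"] = sorted(members)
    return names, tfs, modules


def generate_interactome(config: CohortConfig) -> tuple[nx.Graph, dict[str, set[str]]]:
    """Scale-free interactome with planted, densified pathway modules.

    A preferential-attachment backbone supplies the heavy-tailed degree
    distribution (so the hub filter has something to bite on); each planted
    module is densified with extra high-confidence internal edges and
    exported as a gene set. Edge confidences lie in (0, 1]; no self-loops.
    """
    names, tfs, modules = _layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m_attach = min(3, config.n_proteins - 1)
    backbone = nx.barabasi_albert_graph(
        config.n_proteins, m_attach, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(backbone, {i: names[i] for i in range(config.n_proteins)})
    for u, v in g.edges():
        g.edges[u, v]["weight"] = float(rng.uniform(0.4, 0.8))
        g.edges[u, v]["origin"] = REFERENCE
    p_intra = 0.35
    for members in modules.values():
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                if not g.has_edge(u, v) and rng.random() < p_intra:
                    g.add_edge(u, v, weight=float(rng.uniform(0.7, 0.95)), origin=REFERENCE)
    # TFs physically co-complex with proteins of the module they regulate
    module_ids = sorted(modules)
    for j, tf in enumerate(tfs):
        members = modules[module_ids[j % len(module_ids)]]
        anchors = rng.choice(members, size=min(3, len(members)), replace=False)
        for v in anchors:
            if not g.has_edge(tf, v):
                g.add_edge(tf, str(v), weight=float(rng.uniform(0.6, 0.9)), origin=REFERENCE)
    return g, {name: set(members) for name, members in modules.items()}


def _class_modules(config: CohortConfig) -> dict[int, list[str]]:
    """Cyclic module assignment: class k perturbs modules k and k+1 (mod K).

    Adjacent MoA classes therefore share one pathway module, mirroring real
    mechanism classes whose downstream pathways partially overlap; this
    gives the cohort a graded mechanism space (identical / adjacent /
    disjoint module sets) rather than an all-or-nothing one.
    """
    k_tot = config.n_moa_classes
    return {
        k: sorted({f"module_{k:02d}", f"module_{(k + 1) % k_tot:02d}"})
        for k in range(k_tot)
    }


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Build the full synthetic study, deterministic given the seed."""
    names, tfs, modules = _layout(config)
    interactome, gene_sets = generate_interactome(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    class_mods = _class_modules(config)
    drugs = [f"drug{i:02d}" for i in range(config.n_drugs)]
    moa_labels = {d: f"moa{(i % config.n_moa_classes):02d}" for i, d in enumerate(drugs)}
    truth = {d: list(class_mods[i % config.n_moa_classes]) for i, d in enumerate(drugs)}
    cell_lines = [f"CL{c:02d}" for c in range(config.n_cell_lines)]
    module_ids = sorted(modules)

    # TF regulons: each TF is wired to >=3 genes of its module plus background
    regnet: dict[str, set[str]] = {}
    non_module = sorted(set(names) - set().union(*modules.values()) - set(tfs))
    for j, tf in enumerate(tfs):
        mod = modules[module_ids[j % len(module_ids)]]
        n_in = min(6, len(mod))
        targets = set(rng.choice(mod, size=n_in, replace=False))
        if non_module:
            targets |= set(rng.choice(non_module, size=min(2, len(non_module)), replace=False))
        regnet[tf] = targets

    drug_targets = {
        d: set(rng.choice(modules[truth[d][0]], size=2, replace=False)) for d in drugs
    }

    # per-gene perturbation sign, fixed per drug
    sign: dict[str, dict[str, int]] = {}
    perturbed: dict[str, set[str]] = {}
    for d in drugs:
        genes = sorted(set().union(*(modules[m] for m in truth[d])))
        perturbed[d] = set(genes)
        sign[d] = {g_: int(rng.choice([-1, 1])) for g_ in genes}

    lo, hi = config.baseline_range
    panels: dict[tuple[str, str], ExpressionPanel] = {}
    phospho_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for cl in cell_lines:
        baseline = rng.uniform(lo, hi, size=config.n_proteins)
        for d in drugs:
            control = baseline[:, None] + rng.normal(
                0, config.noise_sd, size=(config.n_proteins, config.n_replicates)
            )
            shift = np.array(
                [config.effect_size * sign[d].get(g_, 0) for g_ in names]
            )
            treated = (baseline + shift)[:, None] + rng.normal(
                0, config.noise_sd, size=(config.n_proteins, config.n_replicates)
            )
            panels[(cl, d)] = ExpressionPanel(
                genes=list(names),
                treated=treated,
                control=control,
                condition=(cl, d),
            )
            phospho_tables[(cl, d)] = _phospho_table(config, rng, d, perturbed, non_module)

    # localization correlated with module membership
    compartments = [f"compartment{c:02d}" for c in range(config.n_compartments)]
    localization: dict[str, set[str]] = {}
    for m_idx, mid in enumerate(module_ids):
        comp = compartments[m_idx % len(compartments)]
        for g_ in modules[mid]:
            localization[g_] = {comp}
    for j, tf in enumerate(tfs):
        comp = compartments[(j % len(module_ids)) % len(compartments)]
        localization[tf] = {comp, compartments[0]}
    for g_ in non_module:
        k = int(rng.integers(1, 3))
        localization[g_] = set(rng.choice(compartments, size=k, replace=False))
    unlocalized = rng.random(config.n_proteins) < config.frac_unlocalized
    for g_, drop in zip(names, unlocalized):
        if drop:
            localization.pop(g_, None)

    # sensitivity: z negative when the drug's modules hit the cell line's
    # driver modules; graded by the fraction of modules on-target
    driver_mods = {
        cl: set(class_mods[c % config.n_moa_classes]) for c, cl in enumerate(cell_lines)
    }
    sensitivity: dict[tuple[str, str], float] = {}
    for cl in cell_lines:
        for d in drugs:
            frac = len(set(truth[d]) & driver_mods[cl]) / len(truth[d])
            sensitivity[(cl, d)] = float(1.5 - 3.5 * frac + rng.normal(0, 0.4))

    driver_pool = sorted(
        set().union(*(modules[m] for mods in class_mods.values() for m in mods))
    )
    n_drivers = max(10, len(driver_pool) // 5)
    driver_genes = set(rng.choice(driver_pool, size=min(n_drivers, len(driver_pool)), replace=False))

    return CohortBundle(
        config=config,
        interactome=interactome,
        panels=panels,
        phospho_tables=phospho_tables,
        regnet=regnet,
        drug_targets=drug_targets,
        localization=localization,
        gene_sets=gene_sets,
        moa_labels=moa_labels,
        driver_genes=driver_genes,
        sensitivity=sensitivity,
        truth=truth,
    )


def _phospho_table(
    config: CohortConfig,
    rng: np.random.Generator,
    drug: str,
    perturbed: Mapping[str, set[str]],
    non_module: list[str],
) -> pd.DataFrame:
    """Per-condition phosphosite read-outs: true hits plus null background."""
    rows = []
    signal = config.effect_size > 0
    for prot in sorted(perturbed[drug]):
        if rng.random() < config.frac_phospho:
            if signal:
                fc = float(rng.choice([-1, 1]) * (config.effect_size + rng.normal(0, config.noise_sd)))
                p = float(rng.uniform(0.0, 0.04))
            else:
                fc = float(rng.normal(0, config.noise_sd))
                p = float(rng.uniform(0.0, 1.0))
            rows.append({"protein": prot, "fold_change": fc, "p_value": p})
    n_bg = min(30, len(non_module))
    for prot in rng.choice(non_module, size=n_bg, replace=False):
        rows.append(
            {
                "protein": str(prot),
                "fold_change": float(rng.normal(0, config.noise_sd)),
                "p_value": float(rng.uniform(0.0, 1.0)),
            }
        )
    return pd.DataFrame(rows, columns=["protein", "fold_change", "p_value"])
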