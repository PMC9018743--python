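"""Turn one condition's omics read-outs into a prized terminal set.

Three evidence streams feed the prize-collecting solver:

* transcription factors whose regulons are enriched for differentially
  expressed genes (``source="tf"``),
* proteins with significantly changed phosphosites (``source="phospho"``),
* the drug's known targets (``source="drug_target"``).

Prizes quantify how strongly the condition implicates each protein and are
always non-negative; the solver's prize function scales them by β later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionPanel",
    "DiffExprResult",
    "TerminalSet",
    "InfeasibleCondition",
    "differential_expression",
    "select_tf_terminals",
    "select_phospho_terminals",
    "assemble_terminal_set",
]

_LOG_EPS = 1e-9  # floor for arm means before taking log2 (fluorescence scale)


class InfeasibleCondition(ValueError):
    """Raised when a condition yields no usable terminal evidence."""


@dataclass
class ExpressionPanel:
    """Replicate fluorescence values for one (cell line, drug) condition.

    ``treated`` and ``control`` are (genes x replicates) arrays aligned to
    ``genes``; the control arm is the vehicle (DMSO) treatment.
    """

    genes: list[str]
    treated: np.ndarray
    control: np.ndarray
    condition: tuple[str, str]

    def __post_init__(self) -> None:
        self.treated = np.asarray(self.treated, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if self.treated.shape[0] != len(self.genes) or self.control.shape[0] != len(self.genes):
            raise ValueError("value matrices must have one row per gene")
        if self.treated.shape[1] < 2 or self.control.shape[1] < 2:
            raise ValueError("need >=2 replicates per arm")
        if not (np.isfinite(self.treated).all() and np.isfinite(self.control).all()):
            raise ValueError("non-finite fluorescence values")

    @property
    def condition_id(self) -> str:
        return f"{self.condition[0]}_{self.condition[1]}"


@dataclass
class DiffExprResult:
    """Per-gene one-way ANOVA p-values and log2 fold changes."""

    table: pd.DataFrame  # index: gene; columns: p_value, log2fc, significant
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def log2fc_of(self, genes: Iterable[str]) -> pd.Series:
        return self.table.loc[list(genes), "log2fc"]


@dataclass
class TerminalSet:
    """Prized proteins for one condition; houses p(v) of the prize function."""

    entries: dict[str, tuple[float, str]] = field(default_factory=dict)
    condition: str = ""

    def __post_init__(self) -> None:
        for prot, (prize, _src) in self.entries.items():
            if prize < 0:
                raise ValueError(f"negative prize for {prot}")

    def prizes(self) -> dict[str, float]:
        return {p: prize for p, (prize, _s) in self.entries.items()}

    def sources(self) -> dict[str, str]:
        return {p: src for p, (_z, src) in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


def differential_expression(panel: ExpressionPanel, alpha: float = 0.05) -> DiffExprResult:
    """One-way ANOVA of treated vs control replicates, per gene.

    With two groups the ANOVA F statistic is the squared pooled-variance
    two-sample t, so p-values agree with a two-sided t-test. The log2 fold
    change is ``log2(mean treated) - log2(mean control)`` on arm means (not
    the mean of per-replicate logs), with means floored at a tiny epsilon to
    keep the ratio defined on the fluorescence scale.

    Degenerate genes with zero variance in both arms get p = 1 when the arm
    means are equal and p = 0 when they differ.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    t, c = panel.treated, panel.control
    mt, mc = t.mean(axis=1), c.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(np.maximum(mt, _LOG_EPS)) - np.log2(np.maximum(mc, _LOG_EPS))

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.f_oneway(t, c, axis=1)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(mt, mc)
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    df = pd.DataFrame(
        {"p_value": p, "log2fc": log2fc, "significant": p < alpha},
        index=pd.Index(panel.genes, name="gene"),
    )
    return DiffExprResult(df, alpha)


def select_tf_terminals(
    diff: DiffExprResult,
    regnet: Mapping[str, set[str]],
    min_targets: int = 3,
) -> TerminalSet:
    """Pick TFs regulating enough significantly transcribed genes.

    A TF becomes a terminal iff at least ``min_targets`` of its regulated
    genes are significant; its prize is the mean absolute log2 fold change
    over those significant regulated genes.
    """
    if not regnet:
        raise ValueError("empty regulatory network")
    sig = set(diff.significant_genes)
    entries: dict[str, tuple[float, str]] = {}
    for tf in sorted(regnet):
        hits = sorted(set(regnet[tf]) & sig)
        if len(hits) >= min_targets:
            prize = float(diff.log2fc_of(hits).abs().mean())
            entries[tf] = (prize, "tf")
    return TerminalSet(entries)


def select_phospho_terminals(
    phospho: pd.DataFrame, alpha: float = 0.05
) -> TerminalSet:
    """Pick proteins with significantly changed phosphosites.

    ``phospho`` has columns ``protein``, ``fold_change``, ``p_value`` with
    one row per phosphosite. Sites with p < alpha are kept; multiple
    significant sites on one protein collapse to the maximum absolute fold
    change, which becomes the prize.
    """
    entries: dict[str, tuple[float, str]] = {}
    if len(phospho):
        sig = phospho[phospho["p_value"] < alpha]
        if len(sig):
            best = sig.assign(absfc=sig["fold_change"].abs()).groupby("protein")["absfc"].max()
            entries = {p: (float(v), "phospho") for p, v in best.sort_index().items()}
    return TerminalSet(entries)


def assemble_terminal_set(
    tf_part: TerminalSet,
    phospho_part: TerminalSet,
    targets: Iterable[str],
    condition: str = "",
) -> TerminalSet:
    """Merge evidence streams into the final terminal set.

    Proteomic evidence wins conflicts (a protein in both lists keeps its
    phospho prize). Drug targets are then appended with a uniform prize
    equal to the mean prize of the omics-derived entries (1.0 when there are
    none), so targets are anchored without dominating.

    Raises :class:`InfeasibleCondition` when there is no evidence at all —
    conditions with empty seed lists cannot support network reconstruction
    and are dropped upstream.
    """
    targets = sorted(set(targets))
    entries = dict(tf_part.entries)
    entries.update(phospho_part.entries)  # phospho precedence
    if not entries:
        if not targets:
            raise InfeasibleCondition(
                f"condition {condition or '<unnamed>'}: no terminals from any source"
            )
        raise InfeasibleCondition(
            f"condition {condition or '<unnamed>'}: no omics-derived terminals; "
            "seed list too small for network modeling"
        )
    uniform = float(np.mean([p for p, _ in entries.values()])) if entries else 1.0
    for t in targets:
        entries[t] = (uniform, "drug_target")
    return TerminalSet(entries, condition=condition)
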