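"""Drug-level evaluation of network separation.

Separation scores become a classifier of drug-pair mechanism: two conditions
are predicted mechanistically *similar* when their networks overlap
(s_AB below a threshold). Sweeping the threshold yields ROC / precision-
recall curves against mechanism-of-action (MoA) labels, with the operating
point chosen by Matthews correlation coefficient (MCC) because same-MoA
pairs are heavily outnumbered. The module also rates candidate drug
combinations by the complementary-exposure rule and relates separation to
drug-sensitivity differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .compare import SeparationMatrix
from .enrichment import EnrichmentRecord, shared_pathways

__all__ = [
    "ClassificationMetrics",
    "CombinationCandidate",
    "SweepResult",
    "RegressionResult",
    "metrics_from_counts",
    "classify_pairs",
    "sweep_thresholds",
    "tanimoto",
    "predict_combinations",
    "sensitivity_association",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    accuracy: float
    sensitivity: float
    specificity: float
    tpr: float
    fpr: float
    f1: float
    mcc: float
    threshold: float = float("nan")
    degenerate: bool = False  # no positive predictions at this threshold


def metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int, threshold: float = float("nan")
) -> ClassificationMetrics:
    """All benchmark metrics from a confusion matrix.

    MCC is defined as 0 when any marginal is empty; precision is reported
    as 0 (with ``degenerate=True``) when nothing is predicted positive.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    pp, pn = tp + fp, fn + tn  # predicted positives/negatives
    pos, neg = tp + fn, fp + tn
    total = tp + fp + fn + tn
    degenerate = pp == 0
    precision = tp / pp if pp else 0.0
    recall = tp / pos if pos else 0.0
    accuracy = (tp + tn) / total if total else 0.0
    specificity = tn / neg if neg else 0.0
    fpr = fp / neg if neg else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = pp * pos * neg * pn
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return ClassificationMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, accuracy=accuracy,
        sensitivity=recall, specificity=specificity,
        tpr=recall, fpr=fpr, f1=f1, mcc=mcc,
        threshold=threshold, degenerate=degenerate,
    )


def _labeled_pairs(m: SeparationMatrix) -> pd.DataFrame:
    """Unordered condition pairs with s_ab and same-MoA ground truth."""
    if "moa" not in m.meta.columns:
        raise ValueError("separation matrix lacks MoA metadata")
    if m.meta["moa"].isna().any():
        raise ValueError("unlabeled drug(s) in MoA metadata")
    pairs = m.pairs().dropna(subset=["s_ab"])
    moa = m.meta["moa"]
    pairs = pairs.assign(
        same_moa=[moa[a] == moa[b] for a, b in zip(pairs["a"], pairs["b"])]
    )
    return pairs


def classify_pairs(
    m: SeparationMatrix,
    threshold: float,
) -> ClassificationMetrics:
    """Benchmark separation against MoA labels at one threshold.

    A pair is predicted similar iff s_ab < threshold (strict). Same-MoA &
    similar = TP, different-MoA & similar = FP, same-MoA & separated = FN,
    different-MoA & separated = TN.
    """
    pairs = _labeled_pairs(m)
    similar = pairs["s_ab"] < threshold
    tp = int((pairs["same_moa"] & similar).sum())
    fp = int((~pairs["same_moa"] & similar).sum())
    fn = int((pairs["same_moa"] & ~similar).sum())
    tn = int((~pairs["same_moa"] & ~similar).sum())
    return metrics_from_counts(tp, fp, fn, tn, threshold=threshold)


@dataclass
class SweepResult:
    table: pd.DataFrame  # one row per threshold with all metrics
    best: ClassificationMetrics
    auc: float
    degenerate_labels: bool = False  # single-class ground truth


def sweep_thresholds(
    m: SeparationMatrix,
    thresholds: Sequence[float],
) -> SweepResult:
    """ROC / PR sweep over separation-score thresholds; best point by MCC.

    Ties in MCC resolve toward the smaller threshold. The AUC uses -s_ab as
    the similarity score for the same-MoA label. A single-class ground
    truth yields a degenerate ROC, flagged rather than raised.
    """
    if len(thresholds) < 1:
        raise ValueError("need at least one threshold")
    thresholds = sorted(thresholds)
    rows = [classify_pairs(m, t) for t in thresholds]
    table = pd.DataFrame([r.__dict__ for r in rows])
    best = max(rows, key=lambda r: (r.mcc, -r.threshold))
    pairs = _labeled_pairs(m)
    y = pairs["same_moa"].to_numpy(dtype=bool)
    degenerate = y.all() or (~y).all()
    if degenerate:
        warnings.warn("single-class MoA ground truth; ROC undefined (AUC := nan)")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, -pairs["s_ab"].to_numpy(dtype=float)))
    return SweepResult(table=table, best=best, auc=auc, degenerate_labels=degenerate)


def tanimoto(fp_a: Iterable, fp_b: Iterable) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two binary fingerprint sets."""
    a, b = set(fp_a), set(fp_b)
    if not (a | b):
        raise ValueError("both fingerprints empty")
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class CombinationCandidate:
    pair: tuple[str, str]
    s_ab: float
    shared_pathways: int
    n_nodes_a: int
    n_nodes_b: int
    shared_drivers: int
    passes_rating: bool
    passes_driver_rule: bool


def predict_combinations(
    networks: Mapping[str, Iterable[str]],
    enrichments: Mapping[str, Sequence[EnrichmentRecord]],
    m: SeparationMatrix,
    drivers: Iterable[str],
    *,
    min_nodes: int = 40,
    large_nodes: int = 100,
    max_shared_pathways: int = 2,
) -> list[CombinationCandidate]:
    """Rate condition pairs as potential drug combinations.

    The complementary-exposure rating requires separated networks
    (s_ab > 0), fewer than ``max_shared_pathways`` shared significant
    signaling pathways, both networks larger than ``min_nodes`` and at least
    one larger than ``large_nodes``. The driver rule additionally asks for a
    shared cancer-driver protein between two separated networks. Candidates
    are ranked by descending s_ab.
    """
    driver_set = set(drivers)
    out: list[CombinationCandidate] = []
    for _, row in m.pairs().dropna(subset=["s_ab"]).iterrows():
        a, b = row["a"], row["b"]
        if a not in enrichments or b not in enrichments:
            warnings.warn(f"pair ({a}, {b}) skipped: missing enrichment")
            continue
        nodes_a, nodes_b = set(networks[a]), set(networks[b])
        shared = len(shared_pathways(enrichments[a], enrichments[b]))
        n_shared_drivers = len(nodes_a & nodes_b & driver_set)
        s_ab = float(row["s_ab"])
        separated = s_ab > 0.0
        rating = (
            separated
            and shared < max_shared_pathways
            and len(nodes_a) > min_nodes
            and len(nodes_b) > min_nodes
            and max(len(nodes_a), len(nodes_b)) > large_nodes
        )
        out.append(
            CombinationCandidate(
                pair=(a, b),
                s_ab=s_ab,
                shared_pathways=shared,
                n_nodes_a=len(nodes_a),
                n_nodes_b=len(nodes_b),
                shared_drivers=n_shared_drivers,
                passes_rating=rating,
                passes_driver_rule=separated and n_shared_drivers >= 1,
            )
        )
    out.sort(key=lambda c: (-c.s_ab, c.pair))
    return out


@dataclass(frozen=True)
class RegressionResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def sensitivity_association(
    m: SeparationMatrix,
    sens: Mapping[tuple[str, str], float],
    ss_floor: float = -0.45,
) -> RegressionResult:
    """Regress separation on drug-sensitivity difference over mixed pairs.

    Keeps condition pairs where one drug has a negative sensitivity z-score
    on its cell line (sensitive) and the other a positive one (insensitive),
    and where s_ab exceeds ``ss_floor``. Returns the Pearson correlation of
    s_ab against |Δz| with its two-sided p-value.
    """
    cl, drug = m.meta["cell_line"], m.meta["drug"]
    xs, ys = [], []
    for _, row in m.pairs().dropna(subset=["s_ab"]).iterrows():
        a, b = row["a"], row["b"]
        key_a, key_b = (cl[a], drug[a]), (cl[b], drug[b])
        if key_a not in sens or key_b not in sens:
            continue
        za, zb = sens[key_a], sens[key_b]
        if za * zb >= 0:  # need one sensitive, one insensitive
            continue
        if row["s_ab"] <= ss_floor:
            continue
        xs.append(abs(za - zb))
        ys.append(float(row["s_ab"]))
    if len(xs) < 3:
        raise ValueError(f"insufficient data: only {len(xs)} pairs after filtering")
    fit = stats.linregress(xs, ys)
    return RegressionResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(xs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
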