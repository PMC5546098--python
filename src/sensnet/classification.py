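"""Sensitization classifiers and their evaluation.

Two baseline models:

* a structural-alert heuristic — predict sensitizer iff the chemical fires
  at least one of the five mechanism alerts AND its molecular weight is
  below a bioavailability cutoff (500 Da by default);
* a threshold-KNN read-across — a chemical's neighbors are all other
  chemicals with Tanimoto similarity at or above a minimum similarity T;
  the majority neighbor label is predicted, ties go to sensitizer, and a
  chemical with no neighbors abstains.

Evaluation is leave-one-out over labeled chemicals, pooling predictions
into a confusion matrix with sensitivity, specificity, balanced accuracy
and accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import ChemicalRecord, NON_SENSITIZER, SENSITIZER
from .network import ModulePartition, UNDEFINED_MODULE
from .similarity import pairwise_tanimoto

ABSTAIN = "abstain"


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled 2x2 confusion counts with derived metrics.

    Metrics whose denominator is empty (no actual positives, say) are None.
    """

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_predicted(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def balanced_accuracy(self) -> float | None:
        s, p = self.sensitivity, self.specificity
        return (s + p) / 2 if s is not None and p is not None else None

    @property
    def accuracy(self) -> float | None:
        n = self.n_predicted
        return (self.tp + self.tn) / n if n else None


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | int | None]:
    """Derived metrics of a confusion matrix, with display rounding.

    n/a (None) where a denominator is empty; requires >= 1 prediction.
    """
    if counts.n_predicted < 1:
        raise ValueError("no predictions to evaluate")

    def rnd(x: float | None) -> float | None:
        return None if x is None else round(x, 2)

    return {
        "n_predicted": counts.n_predicted,
        "sensitivity": counts.sensitivity,
        "specificity": counts.specificity,
        "balanced_accuracy": counts.balanced_accuracy,
        "accuracy": counts.accuracy,
        "sensitivity_2dp": rnd(counts.sensitivity),
        "specificity_2dp": rnd(counts.specificity),
        "balanced_accuracy_2dp": rnd(counts.balanced_accuracy),
        "accuracy_2dp": rnd(counts.accuracy),
    }


# ---------------------------------------------------------------------------
# heuristic model

@dataclass(frozen=True)
class HeuristicConfig:
    """Alert + molecular-weight heuristic parameters.

    mw_cutoff: predictions flip to non-sensitizer at MW >= cutoff (strictly
    below the cutoff counts as bioavailable). Alerts are counted over the
    five mechanism flags; RD is excluded as their OR.
    """

    mw_cutoff: float = 500.0

    def __post_init__(self) -> None:
        if not self.mw_cutoff > 0:
            raise ValueError("mw_cutoff must be > 0")


def heuristic_predict(alert_count: int, mw: float,
                      config: HeuristicConfig = HeuristicConfig()) -> str:
    """Predict sensitizer iff alert_count > 0 and MW < cutoff."""
    if not mw > 0:
        raise ValueError(f"molecular weight must be > 0, got {mw}")
    if alert_count < 0:
        raise ValueError("alert_count must be >= 0")
    return SENSITIZER if alert_count > 0 and mw < config.mw_cutoff else NON_SENSITIZER


def evaluate_heuristic(chems: Sequence[ChemicalRecord],
                       config: HeuristicConfig = HeuristicConfig()
                       ) -> tuple[ConfusionCounts, dict[str, str]]:
    """Heuristic predictions and pooled confusion counts over labeled chemicals.

    Unknown-label chemicals receive predictions but never enter the counts.
    """
    predictions: dict[str, str] = {}
    tp = tn = fp = fn = 0
    for c in chems:
        if c.alert_flags is None or c.mw is None:
            raise ValueError(f"chemical {c.id!r} lacks alert flags or MW")
        pred = heuristic_predict(c.alert_flags.alert_count, c.mw, config)
        predictions[c.id] = pred
        if c.label == SENSITIZER:
            tp, fn = tp + (pred == SENSITIZER), fn + (pred == NON_SENSITIZER)
        elif c.label == NON_SENSITIZER:
            tn, fp = tn + (pred == NON_SENSITIZER), fp + (pred == SENSITIZER)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn), predictions


# ---------------------------------------------------------------------------
# threshold-KNN model

@dataclass(frozen=True)
class KNNConfig:
    """Threshold-KNN parameters.

    min_similarity: the minimum Tanimoto similarity T for a chemical to
    count as a neighbor. neighbor_rule selects inclusive (">=", default)
    or strict (">") comparison against T. Ties predict sensitizer; the
    chemical itself never votes (leave-one-out).
    """

    min_similarity: float = 0.9
    neighbor_rule: str = ">="
    self_exclude: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must lie in [0, 1]")
        if self.neighbor_rule not in (">=", ">"):
            raise ValueError('neighbor_rule must be ">=" or ">"')


def knn_predict(neighbor_labels: Iterable[str],
                config: KNNConfig = KNNConfig()) -> str:
    """Majority vote over neighbor labels; tie -> sensitizer; none -> abstain."""
    votes = Counter(neighbor_labels)
    n_sens = votes.get(SENSITIZER, 0)
    n_non = votes.get(NON_SENSITIZER, 0)
    if n_sens + n_non == 0:
        return ABSTAIN
    return SENSITIZER if n_sens >= n_non else NON_SENSITIZER


def _label_vector(chems: Sequence[ChemicalRecord]) -> np.ndarray:
    labs = np.empty(len(chems), dtype=object)
    for i, c in enumerate(chems):
        if c.label not in (SENSITIZER, NON_SENSITIZER):
            raise ValueError(f"chemical {c.id!r} has no binary label")
        labs[i] = c.label
    return labs


def _counts_at(sim: np.ndarray, labels: np.ndarray,
               config: KNNConfig) -> tuple[ConfusionCounts, int]:
    is_sens = labels == SENSITIZER
    if config.neighbor_rule == ">=":
        neigh = sim >= config.min_similarity
    else:
        neigh = sim > config.min_similarity
    if config.self_exclude:
        np.fill_diagonal(neigh, False)
    sens_votes = neigh.astype(np.int64) @ is_sens.astype(np.int64)
    non_votes = neigh.sum(axis=1) - sens_votes
    any_neigh = (sens_votes + non_votes) > 0
    pred_sens = sens_votes >= non_votes  # tie -> sensitizer
    tp = int(np.sum(any_neigh & is_sens & pred_sens))
    fn = int(np.sum(any_neigh & is_sens & ~pred_sens))
    tn = int(np.sum(any_neigh & ~is_sens & ~pred_sens))
    fp = int(np.sum(any_neigh & ~is_sens & pred_sens))
    return (ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn),
            int(np.sum(~any_neigh)))


def evaluate_knn(chems: Sequence[ChemicalRecord],
                 config: KNNConfig = KNNConfig()
                 ) -> tuple[ConfusionCounts, int]:
    """Leave-one-out threshold-KNN evaluation.

    Every chemical is predicted from all *other* labeled chemicals within
    the similarity bound; chemicals with no neighbor abstain and are
    excluded from the counts. Returns (pooled counts, abstention count).
    """
    if len(chems) < 2:
        raise ValueError("need at least 2 chemicals for leave-one-out KNN")
    labels = _label_vector(chems)
    sim = pairwise_tanimoto(chems)
    return _counts_at(sim, labels, config)


def threshold_sweep(chems: Sequence[ChemicalRecord],
                    thresholds: Sequence[float],
                    neighbor_rule: str = ">=") -> pd.DataFrame:
    """Evaluate the KNN at several minimum-similarity thresholds.

    One row per threshold with the confusion counts and derived metrics;
    chemicals are counted only if they have >= 1 neighbor at that threshold.
    The similarity matrix is computed once and shared.
    """
    if len(chems) < 2:
        raise ValueError("need at least 2 chemicals for leave-one-out KNN")
    labels = _label_vector(chems)
    sim = pairwise_tanimoto(chems)
    rows = []
    for t in thresholds:
        cfg = KNNConfig(min_similarity=t, neighbor_rule=neighbor_rule)
        counts, n_abstain = _counts_at(sim, labels, cfg)
        rows.append({
            "min_similarity": t,
            "chemicals": counts.n_predicted,
            "abstained": n_abstain,
            "tp": counts.tp, "tn": counts.tn, "fn": counts.fn, "fp": counts.fp,
            "sensitivity": counts.sensitivity,
            "specificity": counts.specificity,
            "bac": counts.balanced_accuracy,
            "accuracy": counts.accuracy,
        })
    return pd.DataFrame(rows).set_index("min_similarity")


def per_module_performance(partition: ModulePartition,
                           predictions: Mapping[str, str],
                           labels: Mapping[str, str]) -> pd.DataFrame:
    """Module-wise sensitivity/specificity of a set of predictions.

    Rows: each module, Undefined, and a pooled OVERALL row. Metrics whose
    class is absent from a module are n/a (NaN). Only chemicals with binary
    labels and a prediction contribute.
    """
    def counts_for(ids: Iterable[str]) -> ConfusionCounts:
        tp = tn = fp = fn = 0
        for cid in ids:
            lab, pred = labels.get(cid), predictions.get(cid)
            if pred is None or lab not in (SENSITIZER, NON_SENSITIZER):
                continue
            if lab == SENSITIZER:
                tp, fn = tp + (pred == SENSITIZER), fn + (pred != SENSITIZER)
            else:
                tn, fp = tn + (pred != SENSITIZER), fp + (pred == SENSITIZER)
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    def row(name: str, ids: Iterable[str]) -> dict:
        c = counts_for(ids)
        return {"module": name, "n": c.n_predicted,
                "sensitivity": np.nan if c.sensitivity is None else c.sensitivity,
                "specificity": np.nan if c.specificity is None else c.specificity}

    rows = []
    for mid in partition.module_ids:
        rows.append(row(str(mid), partition.members(mid)))
    rows.append(row("Undefined", partition.members(UNDEFINED_MODULE)))
    rows.append(row("OVERALL", list(partition.assignment)))
    return pd.DataFrame(rows).set_index("module")
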