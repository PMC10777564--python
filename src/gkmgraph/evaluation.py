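"""Metric panel and experiment orchestration.

Metrics follow the standard confusion-count definitions: sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy, precision, F1 and the
Matthews correlation coefficient, plus AUC computed with the Mann-Whitney rank
formula

    AUC = (sum_{i in pos} rank_i - n_pos (n_pos + 1) / 2) / (n_pos n_neg)

with average ranks for ties. Ratios with a zero denominator are reported as 0
with a logged warning; AUC on a single-class sample is reported as 0.5 with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from gkmgraph.encoding import EncoderConfig
from gkmgraph.model import ModelConfig, TrainConfig, predict, train_model
from gkmgraph.sequence_io import Dataset, make_folds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive and negative tallies."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricPanel:
    """SN, SP, ACC, PRE, F1 in [0,1]; MCC in [-1,1]; AUC in [0,1]."""

    SN: float
    SP: float
    ACC: float
    PRE: float
    F1: float
    MCC: float
    AUC: float

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        d = {"SN": self.SN, "SP": self.SP, "ACC": self.ACC, "PRE": self.PRE,
             "F1": self.F1, "MCC": self.MCC, "AUC": self.AUC}
        if percent:
            # SN/SP/ACC/PRE/F1/AUC are conventionally reported as percentages;
            # MCC stays on its [-1, 1] scale.
            d = {k: (v * 100.0 if k != "MCC" else v) for k, v in d.items()}
        return d


def confusion_counts(labels: np.ndarray, hard_predictions: np.ndarray) -> ConfusionCounts:
    """Tabulate TP/TN/FP/FN from binary labels and binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(hard_predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    for name, v in (("labels", y), ("predictions", p)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reported as 0", name)
        return 0.0
    return num / den


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank formula with average ranks for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUC undefined with a single class; reported as 0.5")
        return 0.5
    ranks = rankdata(scores, method="average")
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    c: ConfusionCounts, scores: np.ndarray, labels: np.ndarray
) -> MetricPanel:
    """Full metric panel from confusion counts and continuous scores."""
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    sn = _safe_ratio(tp, tp + fn, "SN")
    sp = _safe_ratio(tn, tn + fp, "SP")
    acc = _safe_ratio(tp + tn, c.total, "ACC")
    pre = _safe_ratio(tp, tp + fp, "PRE")
    f1 = _safe_ratio(2 * pre * sn, pre + sn, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return MetricPanel(SN=sn, SP=sp, ACC=acc, PRE=pre, F1=f1, MCC=mcc,
                       AUC=rank_auc(scores, labels))


def evaluate_predictions(
    labels: np.ndarray, scores: np.ndarray, hard: np.ndarray
) -> MetricPanel:
    """Convenience: confusion counts + metric panel in one call."""
    return compute_metrics(confusion_counts(labels, hard), scores, labels)


def _mean_panel(panels: list[MetricPanel]) -> MetricPanel:
    arr = {f: float(np.mean([getattr(p, f) for p in panels]))
           for f in ("SN", "SP", "ACC", "PRE", "F1", "MCC", "AUC")}
    return MetricPanel(**arr)


def cross_validate(
    ds: Dataset,
    enc: EncoderConfig,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    n_folds: int = 10,
) -> tuple[list[MetricPanel], MetricPanel]:
    """Stratified k-fold cross-validation of the full train/predict pipeline.

    Each fold trains on its training part (the held-out part doubles as the
    validation set for the training log) and is scored on the held-out part.
    Returns per-fold panels and their arithmetic mean.
    """
    panels = []
    for train_ds, heldout_ds in make_folds(ds, n_folds, seed=tcfg.seed):
        params, _ = train_model(train_ds, heldout_ds, enc, mcfg, tcfg)
        scores, hard = predict(heldout_ds, enc, params)
        panels.append(evaluate_predictions(heldout_ds.labels, scores, hard))
    return panels, _mean_panel(panels)


def grid_experiment(
    ds: Dataset,
    grid: list[tuple[int, int]],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    n_folds: int = 10,
    count_mode: str = "relative",
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Cross-validate every (k, d) encoder setting and rank the results.

    Selection maximizes mean validation ACC; ties go to the higher AUC, then
    the smaller k. Returns the ranked table (with a ``selected`` column) and
    the chosen pair.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for k, d in grid:
        enc = EncoderConfig(k=k, d=d, count_mode=count_mode)
        _, mean = cross_validate(ds, enc, mcfg, tcfg, n_folds)
        rows.append({"k": k, "d": d, **mean.as_dict()})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["ACC", "AUC", "k"], ascending=[False, False, True], kind="mergesort"
    )
    table = order.reset_index(drop=True)
    table["selected"] = [i == 0 for i in range(len(table))]
    best = (int(table.loc[0, "k"]), int(table.loc[0, "d"]))
    return table, best


def depth_ablation(
    ds: Dataset,
    depths: list[int],
    enc: EncoderConfig,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Cross-validated metric panel per GCN stack depth (no selection).

    Each depth uses the default width schedule unless ``mcfg`` pins explicit
    hidden dims for its own depth.
    """
    if any(not 1 <= m <= 8 for m in depths):
        raise ValueError("depths must lie in [1, 8]")
    rows = []
    for m in depths:
        cfg = ModelConfig(
            n_gcn_layers=m,
            gcn_hidden_dims=None,
            conv_channels=mcfg.conv_channels,
            conv_kernel_size=mcfg.conv_kernel_size,
            fc_hidden_dim=mcfg.fc_hidden_dim,
            use_edge_weights=mcfg.use_edge_weights,
            seed=mcfg.seed,
        )
        _, mean = cross_validate(ds, enc, cfg, tcfg, n_folds)
        rows.append({"n_gcn_layers": m, **mean.as_dict()})
    return pd.DataFrame(rows)
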