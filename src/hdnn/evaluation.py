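"""Confusion-matrix metrics and the imbalance-ratio sweep driver.

Metric conventions (positive class = pre-miRNA, label 1):

* accuracy = (TP + TN) / n;
* sensitivity (SE) = positive-class recall TP / (TP + FN);
* specificity (SP) = negative-class recall TN / (TN + FP);
* F1 and precision are MACRO averaged — the unweighted mean over the two
  classes — with the 0/0 -> 0 convention for undefined per-class values.

Macro averaging gives the minority class equal weight; it is what makes an
all-negative classifier on a 1:4000 table score F1 = precision = 0.50
(perfect on negatives, zero on positives) instead of a misleading ~1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import tree as hdnn_tree
from .ann import NetworkSpec, TrainConfig
from .data_io import FeatureTable, stratified_split
from .errors import DomainError, ShapeError
from .imbalance import ImbalanceSpec, subsample_to_ir, target_counts
from .tree import GrowConfig, grow_tree

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "metrics", "ir_sweep"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    se: float
    sp: float
    f1_macro: float
    prec_macro: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "se": self.se,
            "sp": self.sp,
            "f1": self.f1_macro,
            "prec": self.prec_macro,
        }

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding used in the benchmark tables (2 decimals)."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def confusion(truth: Sequence[int], pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN with 1 as the positive class. Empty input -> zeros."""
    t = np.asarray(truth, dtype=np.int64)
    p = np.asarray(pred, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ShapeError(f"truth {t.shape} and pred {p.shape} must be equal-length 1-D")
    for name, v in (("truth", t), ("pred", p)):
        if v.size and not np.isin(v, (0, 1)).all():
            raise DomainError(f"{name} labels must be in {{0, 1}}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """Derive the metric set from confusion counts (0/0 -> 0 throughout)."""
    if c.n == 0:
        raise DomainError("metrics undefined on an empty evaluation")
    # per-class precision / recall / F1; class 1 first, then class 0
    prec_pos = _safe_div(c.tp, c.tp + c.fp)
    rec_pos = _safe_div(c.tp, c.tp + c.fn)
    prec_neg = _safe_div(c.tn, c.tn + c.fn)
    rec_neg = _safe_div(c.tn, c.tn + c.fp)
    f1_pos = _safe_div(2 * prec_pos * rec_pos, prec_pos + rec_pos)
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg)
    return MetricSet(
        acc=(c.tp + c.tn) / c.n,
        se=rec_pos,
        sp=rec_neg,
        f1_macro=(f1_pos + f1_neg) / 2.0,
        prec_macro=(prec_pos + prec_neg) / 2.0,
    )


def _ratio_seed(seed: int, ratio: int) -> int:
    return int((seed * 2_654_435_761 + ratio) % (2**31 - 1))


def ir_sweep(
    table: FeatureTable,
    ladder: Sequence[int],
    spec: NetworkSpec,
    grow_config: GrowConfig,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Benchmark the hybrid model over a ladder of imbalance ratios.

    For each ratio: subsample the table to the target IR, split it
    (stratified), grow a tree on the training side and score the held-out
    side. Ratios whose subsampled table is too small to split (fewer than 2
    samples in either class) are recorded as ``skipped`` rather than fatal.
    Returns a tidy frame with one row per ratio; deterministic per seed.
    """
    rows = []
    for ratio in ladder:
        ratio_seed = _ratio_seed(seed, ratio)
        n_pos, n_neg = target_counts(table.n_positive, table.n_negative, ratio)
        row: dict = {"ratio": ratio, "n_positive": n_pos, "n_negative": n_neg}
        if n_pos < 2 or n_neg < 2:
            row.update(status="skipped", acc=np.nan, se=np.nan, sp=np.nan,
                       f1=np.nan, prec=np.nan)
            rows.append(row)
            continue
        sub = subsample_to_ir(table, ImbalanceSpec(ratio=ratio, seed=ratio_seed))
        train, test = stratified_split(sub, test_fraction=test_fraction, seed=ratio_seed)
        cfg = replace(grow_config, seed=ratio_seed)
        model = grow_tree(train, spec, cfg)
        pred = hdnn_tree.predict(model, test)
        m = metrics(confusion(test.labels, pred))
        row.update(status="ok", **m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
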