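"""Imbalance-ratio (IR) construction by deterministic undersampling.

An IR of 1:k means one positive hairpin per k pseudo-hairpin negatives.
Benchmarks over a ladder of IRs are built by subsampling a source table:

* primary rule — keep ALL negatives and retain
  ``round_half_up(n_negative / ratio)`` positives;
* fallback — if that exceeds the positives available, keep ALL positives
  and retain ``n_positive * ratio`` negatives (capped at the supply).

Rounding is round-half-up to the nearest integer: it is the unique rule
consistent with every cell of the published count ladders (e.g. 218,154 /
3,000 = 72.72 -> 73 and 218,154 / 4,000 = 54.54 -> 55, where floor fails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable
from .errors import DomainError

__all__ = ["ImbalanceSpec", "target_counts", "subsample_to_ir", "ir_ladder"]

#: IR ladders used by the genome-scale benchmarks. The virus dataset is far
#: smaller (237 positives / 839 negatives), so its ladder stops at 1:400.
LADDERS = {
    "standard": [1, 100, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000],
    "virus": [1, 50, 100, 200, 300, 400],
}


@dataclass(frozen=True)
class ImbalanceSpec:
    """A target imbalance ratio (negatives per positive) plus sampling seed."""

    ratio: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise DomainError(f"imbalance ratio must be >= 1, got {self.ratio}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def target_counts(n_positive: int, n_negative: int, ratio: int) -> tuple[int, int]:
    """Class counts after subsampling to ``1:ratio``.

    Returns ``(n_pos_out, n_neg_out)`` under the primary/fallback rule above.
    """
    if ratio <= 0:
        raise DomainError(f"ratio must be positive, got {ratio}")
    if n_positive < 1 or n_negative < 1:
        raise DomainError("both classes must be non-empty")
    n_pos_out = _round_half_up(n_negative / ratio)
    if n_pos_out <= n_positive:
        return n_pos_out, n_negative
    return n_positive, min(n_positive * ratio, n_negative)


def subsample_to_ir(table: FeatureTable, spec: ImbalanceSpec) -> FeatureTable:
    """Subsample a table to the spec's imbalance ratio.

    The downsampled class is a uniform random subset without replacement
    (seeded, deterministic); the other class is kept in full. Retained rows
    stay in their original order.
    """
    if table.n_positive == 0 or table.n_negative == 0:
        raise DomainError("subsampling requires both classes present")
    n_pos_out, n_neg_out = target_counts(table.n_positive, table.n_negative, spec.ratio)

    rng = np.random.default_rng(spec.seed)
    pos_idx = np.flatnonzero(table.labels == 1)
    neg_idx = np.flatnonzero(table.labels == 0)
    if n_pos_out < len(pos_idx):
        pos_idx = rng.choice(pos_idx, size=n_pos_out, replace=False)
    if n_neg_out < len(neg_idx):
        neg_idx = rng.choice(neg_idx, size=n_neg_out, replace=False)
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    return table.take(keep)


def ir_ladder(dataset_kind: str) -> list[int]:
    """The IR ladder for a dataset family: ``standard`` or ``virus``."""
    try:
        return list(LADDERS[dataset_kind])
    except KeyError:
        raise DomainError(
            f"unknown dataset kind {dataset_kind!r}; expected one of {sorted(LADDERS)}"
        ) from None
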