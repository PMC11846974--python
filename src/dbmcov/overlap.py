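"""Binarized spatial patterns and Dice-kappa overlap.

The orthogonal decomposition assigns each voxel predominantly to one
component, so a component map is binarized by per-voxel argmax ownership of
the W rows.  Overlap between two binarized patterns is quantified with Dice's
kappa, kappa = 2a / (2a + b + c), where a counts voxels common to both
patterns and b, c the voxels unique to each: 0 means disjoint patterns,
1 perfect overlap.  Comparing the PFF-differentiating component of sex-specific
decompositions against the all-subjects one gauges how much each sex drives
the pooled atrophy pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BinarizedPattern", "DiceResult", "binarize", "label_map", "dice_kappa", "sex_overlap_report"]

logger = logging.getLogger(__name__)


@dataclass
class BinarizedPattern:
    """Per-voxel component ownership labels (-1 marks all-zero rows)."""

    labels: np.ndarray  # length m, winning component per voxel
    k: int
    n_zero_rows: int

    def support(self, component: int) -> np.ndarray:
        return self.labels == component


@dataclass
class DiceResult:
    a: int  # voxels common to both patterns
    b: int  # voxels unique to the first
    c: int  # voxels unique to the second
    kappa: float


def label_map(W: np.ndarray) -> BinarizedPattern:
    """Assign every voxel to its maximum-weight component.

    Ties break toward the lowest component index (np.argmax convention;
    logged).  Rows that are entirely zero get label -1 and are excluded from
    every support (counted in ``n_zero_rows``).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    labels = np.argmax(W, axis=1)
    row_max = W.max(axis=1)
    zero = row_max <= 0
    labels = np.where(zero, -1, labels)
    ties = ((W == row_max[:, None]).sum(axis=1) > 1) & ~zero
    if ties.any():
        logger.info("%d voxels had tied weights; lowest component index wins", int(ties.sum()))
    if zero.any():
        logger.info("%d all-zero voxel rows excluded from binarized maps", int(zero.sum()))
    return BinarizedPattern(labels=labels, k=W.shape[1], n_zero_rows=int(zero.sum()))


def binarize(W: np.ndarray, component: int) -> np.ndarray:
    """Boolean indicator of the voxels owned by ``component`` (argmax rule)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if not 0 <= component < W.shape[1]:
        raise ValueError(f"component {component} out of range for k={W.shape[1]}")
    return label_map(W).support(component)


def dice_kappa(A: np.ndarray, B: np.ndarray) -> DiceResult:
    """Dice similarity kappa = 2a / (2a + b + c) of two voxel sets.

    ``A`` and ``B`` are boolean indicators over the same mask (equal length).
    kappa is defined as 0 when both sets are empty.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"patterns live on different mask spaces: {A.shape} vs {B.shape}")
    a = int(np.sum(A & B))
    b = int(np.sum(A & ~B))
    c = int(np.sum(B & ~A))
    denom = 2 * a + b + c
    kappa = 2.0 * a / denom if denom else 0.0
    return DiceResult(a=a, b=b, c=c, kappa=kappa)


def sex_overlap_report(
    all_W: np.ndarray,
    male_W: np.ndarray,
    female_W: np.ndarray,
    selected: dict[str, int],
) -> pd.DataFrame:
    """Dice kappa between the selected components of three decompositions.

    ``selected`` maps 'all'/'male'/'female' to the index of each run's
    group-differentiating component (typically the one whose subject-weight
    GLM has the smallest injection-group p-value).  All three W matrices must
    share the voxel space.  Returns a table of kappa(all, male),
    kappa(all, female) and kappa(male, female).
    """
    for key in ("all", "male", "female"):
        if key not in selected:
            raise ValueError(f"missing selected component for {key!r}")
    sets = {
        "all": binarize(all_W, selected["all"]),
        "male": binarize(male_W, selected["male"]),
        "female": binarize(female_W, selected["female"]),
    }
    for name, s in sets.items():
        if not s.any():
            logger.warning("selected %s component owns no voxels; kappa will be 0", name)
    rows = []
    for x, y in (("all", "male"), ("all", "female"), ("male", "female")):
        res = dice_kappa(sets[x], sets[y])
        rows.append(
            {"pattern_a": x, "pattern_b": y, "a": res.a, "b": res.b, "c": res.c, "kappa": res.kappa}
        )
    return pd.DataFrame(rows)
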