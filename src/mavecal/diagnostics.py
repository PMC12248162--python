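"""Fit-quality and classification diagnostics.

Two diagnostics accompany a calibration run:

* a normalized CDF distance between the empirical distribution of a
  labeled sample and the fitted mixture for that sample, evaluated as
  real-valued vectors at all unique observed scores,

      d(F, G) = ||F - G||_p / (||F||_p + ||G||_p),    p = 2 by default,

  which lies in [0, 1] and is 0 iff the vectors coincide.  On the
  reference and synonymous samples — the larger, less selection-biased
  sets — a median distance below roughly 0.2 across bootstrap fits is the
  working signal of an acceptable fit;

* contingency-table summaries (positive likelihood ratio and diagnostic
  odds ratio) of evidence direction against ClinVar class, with the
  three-way direction (pathogenic / indeterminate / benign) dichotomized
  as positive-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import LOW_SCORES_ABNORMAL
from .mixture import MixtureFit
from .distributions import sn_cdf

__all__ = [
    "ContingencyTable",
    "UndefinedResultError",
    "normalized_vector_distance",
    "cdf_distance",
    "lr_dor",
]

DIRECTIONS = ("pathogenic", "indeterminate", "benign")


class UndefinedResultError(ZeroDivisionError):
    """A ratio denominator is zero; enable continuity correction to proceed."""


@dataclass
class ContingencyTable:
    """Counts of evidence direction per clinical class.

    Rows are the ClinVar classes (P/LP, B/LB); columns the assigned
    direction (pathogenic, indeterminate, benign).
    """

    plp: tuple[int, int, int]
    blb: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.plp, self.blb):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValueError("each row needs 3 nonnegative counts")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        """Build from a frame indexed by class with the direction columns."""
        return cls(
            plp=tuple(int(df.loc["PLP", d]) for d in DIRECTIONS),
            blb=tuple(int(df.loc["BLB", d]) for d in DIRECTIONS),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.plp, self.blb], index=["PLP", "BLB"], columns=list(DIRECTIONS)
        )


def normalized_vector_distance(f: np.ndarray, g: np.ndarray, p: int = 2) -> float:
    """||f - g||_p / (||f||_p + ||g||_p), with 0/0 defined as 0."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.size == 0:
        raise ValueError("vectors must be nonempty and of equal length")
    denom = np.linalg.norm(f, p) + np.linalg.norm(g, p)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(f - g, p) / denom)


def cdf_distance(
    scores: np.ndarray,
    fit: MixtureFit,
    sample: str,
    p: int = 2,
) -> float:
    """Normalized distance between a sample's empirical and fitted CDFs.

    Both CDFs are evaluated at every unique observed score of the sample;
    the empirical CDF uses the proportion of observations at or below each
    point.  ``sample`` selects the mixture weight (``P``/``B``/``G``/``S``).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("empty sample")
    points = np.unique(scores)
    if points.size < 2:
        raise ValueError("need at least 2 unique scores")
    empirical = np.searchsorted(np.sort(scores), points, side="right") / scores.size
    w = fit.weight_abnormal_per_sample[sample]
    model = w * sn_cdf(points, fit.theta_abnormal) + (1.0 - w) * sn_cdf(
        points, fit.theta_normal
    )
    return normalized_vector_distance(empirical, model, p)


def lr_dor(
    table: ContingencyTable,
    positive_class: str = "pathogenic",
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Positive likelihood ratio and diagnostic odds ratio of a direction.

    The three-way assignment is dichotomized as ``positive_class`` vs the
    rest.  For the pathogenic dichotomization the P/LP row supplies the
    positives; for the benign dichotomization the roles of the two rows
    swap.  A zero denominator raises :class:`UndefinedResultError` unless
    ``continuity_correction`` adds 0.5 to every cell.
    """
    if positive_class not in ("pathogenic", "benign"):
        raise ValueError("positive_class must be 'pathogenic' or 'benign'")
    col = DIRECTIONS.index(positive_class)
    if positive_class == "pathogenic":
        pos_row, neg_row = list(table.plp), list(table.blb)
    else:
        pos_row, neg_row = list(table.blb), list(table.plp)
    if continuity_correction:
        pos_row = [c + 0.5 for c in pos_row]
        neg_row = [c + 0.5 for c in neg_row]
    tp = pos_row[col]
    fn = sum(pos_row) - tp
    fp = neg_row[col]
    tn = sum(neg_row) - fp
    if sum(pos_row) == 0 or sum(neg_row) == 0 or fp == 0 or fn == 0:
        raise UndefinedResultError(
            "zero denominator in LR+/DOR; pass continuity_correction=True to "
            "add 0.5 to every cell"
        )
    lr_plus = (tp / sum(pos_row)) / (fp / sum(neg_row))
    dor = (tp * tn) / (fn * fp)
    return lr_plus, dor
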