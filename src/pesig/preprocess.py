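"""Turn raw matrices and GI50 tables into the analysis-ready representation.

Three steps: collapse multi-probe genes to their per-sample mean,
quantile-normalize cohorts onto a common scale (by default the training
panel's mean-quantile distribution, so patient data land on the scale
the classifier was calibrated on), and dichotomize continuous GI50 into
sensitive/resistant training labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    RESISTANT,
    SENSITIVE,
    ExpressionMatrix,
    ResponseTable,
)

logger = logging.getLogger(__name__)


class DegenerateResponseError(ValueError):
    """GI50 vector admits no sensitive/resistant split (constant input)."""


@dataclass(frozen=True)
class DichotomizationRule:
    """How a GI50 vector was split into binary classes.

    ``method``    'median' when the panel median is unique, 'max_gap'
                  when several samples tie the median (the threshold is
                  then placed at the widest adjacent gap in the sorted
                  GI50 values).
    ``threshold`` -log10 molar GI50 cut point.
    ``polarity``  'high_value_sensitive': GI50 >= threshold -> sensitive
                  (the -log10 scale: larger value = growth inhibited at a
                  lower concentration). 'high_value_resistant' flips this.
    """

    method: str
    threshold: float
    polarity: str = "high_value_sensitive"


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """One row per symbol; multi-probe genes become their per-sample mean."""
    collapsed = matrix.data.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed)


def reference_quantiles(matrix: ExpressionMatrix) -> np.ndarray:
    """Mean-quantile vector of a matrix: mean across samples of the sorted columns."""
    values = matrix.values
    return np.sort(values, axis=0).mean(axis=1)


def quantile_normalize(
    target: ExpressionMatrix,
    reference: ExpressionMatrix | np.ndarray | None = None,
    interpolate: bool = False,
) -> ExpressionMatrix:
    """Force every sample onto a common value distribution, preserving ranks.

    The common distribution is the mean-quantile vector of ``reference``
    when given, else of ``target`` itself.  Ties within a sample receive
    the average of the quantiles they jointly occupy (midrank rule).
    A reference of different length than the target's feature count is
    an error unless ``interpolate`` is set, in which case the reference
    quantile function is linearly interpolated.
    """
    values = target.values
    n_feat, n_samp = values.shape
    if reference is None:
        if n_samp < 2:
            raise ValueError("need >=2 samples or an explicit reference distribution")
        ref = np.sort(values, axis=0).mean(axis=1)
    else:
        ref = (
            reference_quantiles(reference)
            if isinstance(reference, ExpressionMatrix)
            else np.sort(np.asarray(reference, dtype=float))
        )
        if len(ref) != n_feat and not interpolate:
            raise ValueError(
                f"reference has {len(ref)} quantiles but target has {n_feat} "
                "features; pass interpolate=True to resample"
            )
    m = len(ref)
    out = np.empty_like(values)
    for j in range(n_samp):
        ranks = rankdata(values[:, j], method="average")  # 1..n_feat, .5 on ties
        # map rank r in [1, n_feat] onto the reference quantile grid [1, m]
        if m == n_feat:
            grid = ranks
        else:
            grid = 1 + (ranks - 1) * (m - 1) / (n_feat - 1)
        out[:, j] = np.interp(grid, np.arange(1, m + 1), ref)
    return ExpressionMatrix(
        pd.DataFrame(out, index=target.data.index, columns=target.data.columns)
    )


def dichotomize_gi50(
    responses: ResponseTable,
    polarity: str = "high_value_sensitive",
    method: str | None = None,
) -> tuple[pd.Series, DichotomizationRule]:
    """Split a GI50 panel into sensitive/resistant labels.

    The threshold is the panel median when unique. When two or more
    samples equal the median (a split at the median would be ambiguous)
    the threshold moves to the GI50 value bounding the widest gap
    between adjacent sorted values — the rule used here whenever median
    splitting degenerates. ``method`` forces 'median' or 'max_gap'.

    Returns the +-1 label series (resistant=+1) and the rule applied.
    """
    if responses.gi50 is None:
        raise ValueError("dichotomize_gi50 needs a GI50 table, not binary labels")
    gi50 = responses.gi50.astype(float)
    finite = gi50[np.isfinite(gi50)]
    if len(finite) < 4:
        raise ValueError(f"need >=4 finite GI50 values, got {len(finite)}")
    values = np.sort(finite.to_numpy())
    if values[0] == values[-1]:
        raise DegenerateResponseError("all GI50 values equal; no split possible")

    median = float(np.median(values))
    ties_at_median = int(np.sum(values == median))
    if method is None:
        method = "max_gap" if ties_at_median >= 2 else "median"

    if method == "median":
        threshold = median
    elif method == "max_gap":
        distinct = np.unique(values)
        gaps = np.diff(distinct)
        i = int(np.argmax(gaps))
        threshold = float(distinct[i])  # left edge of the widest gap
        if threshold == distinct[0]:
            # a left-edge threshold at the minimum would empty one class;
            # take the right edge of the gap instead
            threshold = float(distinct[i + 1])
            logger.info("max_gap threshold moved to right gap edge %.4g", threshold)
    else:
        raise ValueError(f"unknown dichotomization method {method!r}")

    if polarity == "high_value_sensitive":
        sensitive = gi50 >= threshold
    elif polarity == "high_value_resistant":
        sensitive = gi50 < threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    at_threshold = int((gi50 == threshold).sum())
    if at_threshold:
        logger.info(
            "%d sample(s) exactly at threshold %.4g assigned by the >= rule",
            at_threshold,
            threshold,
        )
    labels = pd.Series(
        np.where(sensitive, SENSITIVE, RESISTANT), index=gi50.index, dtype=int
    )
    if labels.nunique() < 2:
        raise DegenerateResponseError(
            f"threshold {threshold} puts every sample in one class"
        )
    return labels, DichotomizationRule(method=method, threshold=threshold, polarity=polarity)
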