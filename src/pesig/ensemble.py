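"""AUC-weighted ensemble voting over several signatures for one drug.

Every member signature casts a +-1 vote per sample (+1 resistant), the
votes are weighted by each member's AUC on a labelled cohort, and the
sign of the weighted sum makes the call: positive -> resistant,
negative -> sensitive. Samples for which at least 75% of members agree
are flagged as consensus predictions; consensus calls are expected to
be the more reliable ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluate import ValidationReport, predict, score
from .io import RESISTANT, SENSITIVE, ExpressionMatrix
from .signature import SignatureModel

logger = logging.getLogger(__name__)


@dataclass
class EnsembleModel:
    """Member signatures with their AUC weights and the consensus threshold."""

    members: list[tuple[SignatureModel, float]]
    consensus_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs >=1 member")
        if len(self.members) == 1:
            logger.warning("single-member ensemble is degenerate")
        for _, w in self.members:
            if not np.isfinite(w):
                raise ValueError("non-finite member weight")


def fit_weights(
    members: Sequence[SignatureModel],
    cohort_matrix: ExpressionMatrix,
    cohort_truth,
    consensus_threshold: float = 0.75,
) -> EnsembleModel:
    """Weight each member by its AUC on the labelled cohort.

    Weighting on the same cohort that is later predicted mirrors common
    practice but is optimistic; treat the weights as in-sample.
    """
    weighted = []
    for i, model in enumerate(members):
        try:
            rep = score(predict(model, cohort_matrix), cohort_truth)
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed: {exc}") from exc
        if np.isnan(rep.auc):
            raise ValueError("single-class truth: AUC undefined, cannot weight members")
        weighted.append((model, rep.auc))
    return EnsembleModel(members=weighted, consensus_threshold=consensus_threshold)


def ensemble_predict(
    ensemble: EnsembleModel, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Per-sample weighted vote: label, weighted_sum and consensus_flag.

    A weighted sum of exactly zero is called resistant with a warning
    (the sign rule defines only the strict inequalities; a non-response
    call is the safer clinical default). The consensus flag is true iff
    the majority outcome is shared by at least ``consensus_threshold``
    of the members (unweighted).
    """
    votes = []
    for i, (model, _) in enumerate(ensemble.members):
        try:
            votes.append(predict(model, matrix)["label"].to_numpy())
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed: {exc}") from exc
    votes = np.vstack(votes)  # members x samples
    weights = np.array([w for _, w in ensemble.members], dtype=float)
    weighted_sum = weights @ votes
    labels = np.where(weighted_sum > 0, RESISTANT,
                      np.where(weighted_sum < 0, SENSITIVE, RESISTANT))
    n_zero = int(np.sum(weighted_sum == 0.0))
    if n_zero:
        logger.warning(
            "%d sample(s) with an exactly-zero weighted sum called resistant", n_zero
        )
    frac_resistant = np.mean(votes == RESISTANT, axis=0)
    majority_share = np.maximum(frac_resistant, 1.0 - frac_resistant)
    consensus = majority_share >= ensemble.consensus_threshold
    return pd.DataFrame(
        {
            "label": labels.astype(int),
            "weighted_sum": weighted_sum,
            "consensus_flag": consensus,
        },
        index=matrix.sample_ids,
    )


def score_ensemble(
    ensemble: EnsembleModel, matrix: ExpressionMatrix, truth
) -> tuple[ValidationReport, ValidationReport | None, ValidationReport | None]:
    """Overall report plus consensus / non-consensus sub-reports."""
    pred = ensemble_predict(ensemble, matrix)
    if not isinstance(truth, pd.Series):
        truth = pd.Series(list(truth), index=matrix.sample_ids)
    frame = pd.DataFrame(
        {"label": pred["label"], "decision_value": pred["weighted_sum"]},
        index=pred.index,
    )
    overall = score(frame, truth)
    consensus_rep = non_consensus_rep = None
    mask = pred["consensus_flag"].to_numpy()
    if mask.any():
        consensus_rep = score(frame.loc[mask], truth.loc[frame.index[mask]])
    if (~mask).any():
        non_consensus_rep = score(frame.loc[~mask], truth.loc[frame.index[~mask]])
    return overall, consensus_rep, non_consensus_rep


def select_members(
    models: Sequence[SignatureModel],
    reports: Sequence[ValidationReport],
    k: int,
) -> list[SignatureModel]:
    """Top-k models by MCC (ties: overall accuracy, then fewer features)."""
    order = sorted(
        range(len(models)),
        key=lambda i: (
            -reports[i].mcc,
            -reports[i].overall_acc,
            len(models[i].features),
            i,
        ),
    )
    return [models[i] for i in order[:k]]


def write_ensemble_report(
    overall: ValidationReport,
    consensus: ValidationReport | None,
    non_consensus: ValidationReport | None,
    weights: Mapping,
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("member\tauc_weight\n")
        for mid, w in weights.items():
            fh.write(f"{mid}\t{w:.3f}\n")
        fh.write("\nsubset\tMCC\tSensitive\tResistant\tOverall\tn\n")
        for name, rep in (
            ("all", overall),
            ("consensus", consensus),
            ("non_consensus", non_consensus),
        ):
            if rep is None:
                continue
            r = rep.rounded()
            fh.write(
                f"{name}\t{r['mcc']:.2f}\t{r['sensitive']}%\t{r['resistant']}%\t"
                f"{r['overall']}%\t{rep.n}\n"
            )
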