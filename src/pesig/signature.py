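"""Gaussian-kernel SVM signatures by forward feature selection.

A signature is derived for each (C, sigma) pair of a fixed grid —
both hyperparameters range over decades from 1 to 100,000 subject to
C >= sigma, 21 pairs in all. For one pair, forward feature selection
greedily grows a gene list: every remaining candidate is scored by a
stratified k-fold cross-validated criterion (misclassification rate or
log loss) when appended to the incumbent list, and the best candidate
is accepted only if it strictly lowers the criterion.

The kernel is the Gaussian ``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))``
(sigma is the kernel scale; scikit-learn's gamma = 1 / (2 sigma^2)).
Class encoding is resistant = +1, sensitive = -1 so that a positive
decision value votes "resistant" in the downstream ensemble sign rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import RESISTANT, SENSITIVE, ExpressionMatrix

logger = logging.getLogger(__name__)

GRID_VALUES = (1.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0)

_PROB_CLIP = 1e-15


@dataclass(frozen=True)
class Grid:
    """The (C, sigma) hyperparameter grid with the C >= sigma constraint."""

    pairs: tuple[tuple[float, float], ...]


def build_grid() -> Grid:
    """All (C, sigma) decade pairs with C >= sigma: exactly 21 combinations."""
    pairs = tuple(
        (c, s) for c in GRID_VALUES for s in GRID_VALUES if c >= s
    )
    return Grid(pairs=pairs)


def sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma * sigma)


def _design(matrix: ExpressionMatrix, features: list[str]) -> np.ndarray:
    """Samples x features design block for the given genes."""
    missing = [f for f in features if not matrix.has_feature(f)]
    if missing:
        raise KeyError(f"features absent from matrix: {missing}")
    return np.vstack([matrix.feature_vector(f) for f in features]).T


def _check_labels(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot cross-validate")
    smallest = int(counts.min())
    if k > smallest:
        raise ValueError(
            f"k={k} folds exceed the smallest class size {smallest}; "
            f"use k <= {smallest}"
        )


def _fit_svc(x: np.ndarray, y: np.ndarray, C: float, sigma: float) -> SVC:
    clf = SVC(C=C, kernel="rbf", gamma=sigma_to_gamma(sigma))
    clf.fit(x, y)
    return clf


def cv_criterion(
    features: list[str],
    matrix: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    C: float,
    sigma: float,
    criterion: str = "misclassification",
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV estimate of the training criterion.

    misclassification: fraction of held-out samples mispredicted.
    log_loss: mean negative log of the probability assigned to the true
    class, where probabilities come from a logistic (Platt-style) map of
    the SVM decision value fitted on each training fold. Probabilities
    are clipped to [1e-15, 1 - 1e-15].
    """
    y = np.asarray(labels, dtype=int)
    _check_labels(y, k)
    x = _design(matrix, features)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    total = 0.0
    n = 0
    for train_idx, test_idx in splitter.split(x, y):
        clf = _fit_svc(x[train_idx], y[train_idx], C, sigma)
        if criterion == "misclassification":
            pred = clf.predict(x[test_idx])
            total += float(np.sum(pred != y[test_idx]))
        elif criterion == "log_loss":
            d_train = clf.decision_function(x[train_idx])
            platt = LogisticRegression(max_iter=1000)
            platt.fit(d_train[:, None], y[train_idx])
            p = platt.predict_proba(clf.decision_function(x[test_idx])[:, None])
            pos = list(platt.classes_).index(RESISTANT)
            p_true = np.where(y[test_idx] == RESISTANT, p[:, pos], 1.0 - p[:, pos])
            p_true = np.clip(p_true, _PROB_CLIP, 1.0 - _PROB_CLIP)
            total += float(-np.sum(np.log(p_true)))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        n += len(test_idx)
    return total / n


@dataclass
class SignatureModel:
    """A trained signature: ordered gene list + Gaussian-SVM decision function.

    The decision function is stored explicitly (support vectors, dual
    coefficients, intercept, gamma) so that serialized models predict
    identically after a round trip: f(x) = dual_coef . K(SV, x) + b,
    with f(x) > 0 calling the resistant class (ties fall to resistant).
    """

    features: list[str]
    C: float
    sigma: float
    criterion: str
    criterion_value: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    condition_id: int | str | None = None
    seed: int = 0
    trajectory: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("signature needs >=1 feature")
        if self.C < self.sigma:
            raise ValueError(f"grid constraint violated: C={self.C} < sigma={self.sigma}")
        if not np.isfinite(self.criterion_value):
            raise ValueError("criterion value must be finite")

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        kern = rbf_kernel(self.support_vectors, x, gamma=self.gamma)
        return np.asarray(self.dual_coef) @ kern + self.intercept

    def decision_values(self, matrix: ExpressionMatrix) -> np.ndarray:
        return self.decision_function(_design(matrix, self.features))

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        d = self.decision_function(x)
        return np.where(d >= 0.0, RESISTANT, SENSITIVE)


def _finalize_model(
    features: list[str],
    matrix: ExpressionMatrix,
    y: np.ndarray,
    C: float,
    sigma: float,
    criterion: str,
    criterion_value: float,
    trajectory: list[float],
    condition_id,
    seed: int,
) -> SignatureModel:
    x = _design(matrix, features)
    clf = _fit_svc(x, y, C, sigma)
    # sklearn orders classes ascending: classes_[1] == +1 == resistant, so a
    # positive decision value already votes resistant
    return SignatureModel(
        features=list(features),
        C=C,
        sigma=sigma,
        criterion=criterion,
        criterion_value=criterion_value,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        gamma=sigma_to_gamma(sigma),
        condition_id=condition_id,
        seed=seed,
        trajectory=list(trajectory),
    )


def forward_select(
    pool: list[str],
    matrix: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    C: float,
    sigma: float,
    criterion: str = "misclassification",
    seed: int = 0,
    k: int = 5,
    tol: float = 0.0,
    condition_id=None,
) -> SignatureModel:
    """Greedy forward feature selection over a qualified gene pool.

    Each round evaluates every remaining candidate appended to the
    incumbent feature list (candidate order randomized by ``seed``;
    ties go to the first-encountered candidate in that order) and
    accepts the best one iff it lowers the criterion by more than
    ``tol`` (strict improvement by default). Stops when no candidate
    improves.
    """
    if not pool:
        raise ValueError("empty candidate pool")
    y = np.asarray(labels, dtype=int)
    _check_labels(y, k)
    rng = np.random.default_rng(seed)
    remaining = list(dict.fromkeys(g.upper() for g in pool))
    selected: list[str] = []
    incumbent = np.inf
    trajectory: list[float] = []

    while remaining:
        order = list(rng.permutation(len(remaining)))
        best_value, best_gene = np.inf, None
        for idx in order:
            gene = remaining[idx]
            value = cv_criterion(
                selected + [gene], matrix, y, C, sigma, criterion, k, seed
            )
            if value < best_value:  # strict: ties keep the first-encountered
                best_value, best_gene = value, gene
        if best_gene is None or not best_value < incumbent - tol:
            break
        selected.append(best_gene)
        remaining.remove(best_gene)
        incumbent = best_value
        trajectory.append(best_value)
        if incumbent == 0.0:
            break  # criterion floor reached; no strict improvement possible

    return _finalize_model(
        selected, matrix, y, C, sigma, criterion, incumbent, trajectory,
        condition_id, seed,
    )


def derive_signatures(
    pool: list[str],
    matrix: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    criterion: str = "misclassification",
    seed: int = 0,
    k: int = 5,
    condition_id=None,
    pathway_extended: bool = True,
) -> tuple[list[SignatureModel], list[SignatureModel]]:
    """One forward-selection run per (C, sigma) grid pair.

    Pathway-extended runs drop models with fewer than two genes from
    the returned list (they cannot demonstrate the value of pathway
    extension); the dropped models are returned separately for audit.
    Curated-only runs are exempt from the two-gene floor.

    Returns (models, audited_out).
    """
    if not pool:
        raise ValueError("empty qualified gene pool")
    grid = build_grid()
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=len(grid.pairs))
    models: list[SignatureModel] = []
    audited: list[SignatureModel] = []
    for (C, sigma), pair_seed in zip(grid.pairs, pair_seeds):
        model = forward_select(
            pool, matrix, labels, C, sigma, criterion,
            seed=int(pair_seed), k=k, condition_id=condition_id,
        )
        if pathway_extended and len(model.features) < 2:
            audited.append(model)
        else:
            models.append(model)
    if not models:
        logger.warning(
            "all %d grid models audited out (<2 features); nothing to validate",
            len(audited),
        )
    return models, audited
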