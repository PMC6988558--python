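"""Model calibration/validation metrics and sensitivity analysis.

Error partitioning follows the predicted-class denominator convention:

* Type I (false presence)  = #(predicted focal, actually not) / #(predicted focal)
* Type II (false nonpresence) = #(predicted not focal, actually focal) / #(predicted not focal)

Overall error is the multiclass misclassification fraction; for multi-state
responses the focal binarization applies only to the Type I/II partition.
An empty denominator reports an error of 0 with an explicit undefined flag
(a model that never predicts presence has no false-presence opportunities).

Spherical payoff scores probabilistic calibration: the mean over cases of
the probability assigned to the true state divided by the Euclidean norm of
the full predicted probability vector, in [0, 1] with 1 = certain and
always correct.

Sensitivity is measured as entropy reduction: the mutual information, under
the model's own joint distribution, between the response and one covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .bn import (BNModel, ComplexityTriple, complexity, learn_cpts,
                 learn_tan_structure, posterior_batch)
from .discretize import DiscretizedCases


@dataclass
class ModelEvaluation:
    """Confusion analysis plus calibration scores for one model."""

    n_cases: int
    confusion: pd.DataFrame  # actual (rows) x predicted (columns)
    overall_error: float
    type1_error: float
    type2_error: float
    spherical_payoff: float
    complexity: ComplexityTriple
    focal_state: str
    type1_undefined: bool = False
    type2_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "overall_error": self.overall_error,
            "type1_error": self.type1_error,
            "type2_error": self.type2_error,
            "spherical_payoff": self.spherical_payoff,
            "n_nodes": self.complexity.n_nodes,
            "n_links": self.complexity.n_links,
            "n_probabilities": self.complexity.n_probabilities,
        }


@dataclass
class SensitivityReport:
    """Entropy reduction of the response for each covariate, descending."""

    response: str
    rows: list  # (covariate, entropy_reduction_bits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["covariate", "entropy_reduction"])


def _metrics_from_confusion(confusion: np.ndarray, states: tuple, focal: str):
    n = confusion.sum()
    overall = 1.0 - np.trace(confusion) / n
    f = states.index(focal)
    pred_focal = confusion[:, f].sum()
    pred_other = n - pred_focal
    t1_undef = pred_focal == 0
    t2_undef = pred_other == 0
    type1 = 0.0 if t1_undef else (pred_focal - confusion[f, f]) / pred_focal
    fn = confusion[f, :].sum() - confusion[f, f]
    type2 = 0.0 if t2_undef else fn / pred_other
    return float(overall), float(type1), float(type2), bool(t1_undef), bool(t2_undef)


def _confusion_counts(actual: np.ndarray, predicted: np.ndarray, n_states: int) -> np.ndarray:
    flat = actual.astype(np.int64) * n_states + predicted
    return np.bincount(flat, minlength=n_states * n_states).reshape(n_states, n_states)


def spherical_payoff_from_posteriors(post: np.ndarray, actual: np.ndarray) -> float:
    p_true = post[np.arange(len(actual)), actual]
    norms = np.linalg.norm(post, axis=1)
    return float(np.mean(p_true / norms))


def evaluate(model: BNModel, dcases: DiscretizedCases,
             focal_state: str = "RERA") -> ModelEvaluation:
    """Score a fitted model case-by-case against known outcomes.

    Predictions are the dominant posterior state (ties to the earlier
    state); missing covariate values are marginalized during inference.
    """
    if len(dcases) == 0:
        raise ValueError("empty case set")
    states = model.response_states
    actual = dcases.column(model.response)
    post = posterior_batch(model, dcases)
    predicted = post.argmax(axis=1)
    confusion = _confusion_counts(actual, predicted, len(states))
    overall, t1, t2, t1u, t2u = _metrics_from_confusion(confusion, states, focal_state)
    payoff = spherical_payoff_from_posteriors(post, actual)
    return ModelEvaluation(
        n_cases=len(dcases),
        confusion=pd.DataFrame(confusion, index=list(states), columns=list(states)),
        overall_error=overall, type1_error=t1, type2_error=t2,
        spherical_payoff=payoff, complexity=complexity(model),
        focal_state=focal_state, type1_undefined=t1u, type2_undefined=t2u,
    )


def spherical_payoff(model: BNModel, dcases: DiscretizedCases) -> float:
    """Mean p(true state) / ||posterior||_2 over the case file."""
    if len(dcases) == 0:
        raise ValueError("empty case set")
    actual = dcases.column(model.response)
    post = posterior_batch(model, dcases)
    return spherical_payoff_from_posteriors(post, actual)


def kfold_cv(dcases: DiscretizedCases, covariates: list, k: int = 4,
             seed: int = 42, alpha: float = 1.0, focal_state: str = "RERA",
             root: str | None = None) -> ModelEvaluation:
    """Stratified k-fold cross-validation of a TAN specification.

    Folds are stratified by outcome with sizes differing by at most one;
    for each fold both the tree structure and the CPTs are re-learned on
    the remaining folds and scored on the held-out cases.  The summed
    confusion matrix yields the aggregated error partition; spherical
    payoff is the case-weighted mean over folds.  Deterministic given
    ``seed``.  Complexity reports the full-data model.
    """
    n = len(dcases)
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k cases")
    y = dcases.column(dcases.response_col)
    states = tuple(dcases.states[dcases.response_col])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    confusion = np.zeros((len(states), len(states)), dtype=np.int64)
    payoff_sum = 0.0
    for train_idx, test_idx in splitter.split(np.zeros(n), y):
        if len(test_idx) == 0:
            raise ValueError("a fold has no cases")
        train = dcases.subset(train_idx)
        test = dcases.subset(test_idx)
        model = learn_tan_structure(train, covariates, root=root)
        learn_cpts(model, train, alpha=alpha)
        post = posterior_batch(model, test)
        predicted = post.argmax(axis=1)
        actual = test.column(model.response)
        confusion += _confusion_counts(actual, predicted, len(states))
        payoff_sum += spherical_payoff_from_posteriors(post, actual) * len(test_idx)
    overall, t1, t2, t1u, t2u = _metrics_from_confusion(confusion, states, focal_state)
    full_model = learn_cpts(learn_tan_structure(dcases, covariates, root=root),
                            dcases, alpha=alpha)
    return ModelEvaluation(
        n_cases=n,
        confusion=pd.DataFrame(confusion, index=list(states), columns=list(states)),
        overall_error=overall, type1_error=t1, type2_error=t2,
        spherical_payoff=payoff_sum / n, complexity=complexity(full_model),
        focal_state=focal_state, type1_undefined=t1u, type2_undefined=t2u,
    )


def entropy_reduction(model: BNModel, covariate: str) -> float:
    """Mutual information I(response; covariate) under the model's joint, in bits.

    The joint P(response, covariate) is obtained by exact enumeration: for
    each covariate state, the class likelihood of observing just that state
    (all other covariates summed out along the tree).
    """
    if covariate not in model.nodes:
        raise ValueError(f"covariate {covariate!r} not in model")
    states = model.nodes[covariate]
    C = len(model.response_states)
    joint = np.empty((C, len(states)))
    for v in range(len(states)):
        post_unnorm = model.prior * _likelihood_of(model, covariate, v)
        joint[:, v] = post_unnorm
    joint = joint / joint.sum()
    pq = joint.sum(axis=1, keepdims=True)
    pf = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (pq * pf))
    return float(max(np.nansum(term), 0.0))


def _likelihood_of(model: BNModel, covariate: str, code: int) -> np.ndarray:
    from .bn import _class_likelihood
    return _class_likelihood(model, {covariate: code})


def response_entropy(model: BNModel) -> float:
    """H(response) of the model prior, in bits."""
    p = model.prior[model.prior > 0]
    return float(-(p * np.log2(p)).sum())


def sensitivity_report(model: BNModel) -> SensitivityReport:
    """Entropy reduction for every covariate, sorted descending (stable)."""
    rows = [(x, entropy_reduction(model, x)) for x in model.nodes]
    rows.sort(key=lambda r: -r[1])
    return SensitivityReport(model.response, rows)
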