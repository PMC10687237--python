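"""Per-variable linear probability scoring with automatic L2 selection.

Each binary attribute is regressed on the feature matrix with a Bayesian
ridge (evidence/marginal-likelihood maximization chooses the L2 strength);
raw linear scores are returned unclipped — the downstream AUC metric is
rank-based, so no probability calibration is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import BayesianRidge

from ._utils import ConfigError
from .evaluate import make_cv_plan, run_cv
from .features import (
    DemographicsInput,
    EmbeddingInput,
    FaceMetricsInput,
    OvalSpec,
    StackedInput,
    make_backend,
)

__all__ = ["RidgeModel", "fit_auto_ridge", "predict_scores", "nested_input_runner"]


@dataclass
class RidgeModel:
    """Fitted linear probability model with evidence-selected L2 strength."""

    weights: np.ndarray
    intercept: float
    l2_strength: float  # ratio of weight precision to noise precision
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all() or not math.isfinite(self.intercept):
            raise ConfigError("ridge fit produced non-finite parameters")
        if not self.l2_strength > 0:
            raise ConfigError("regularization strength must be positive")


def fit_auto_ridge(
    features: np.ndarray, y: np.ndarray, max_iter: int = 300, tol: float = 1e-3
) -> RidgeModel:
    """Bayesian ridge fit of a binary target on a feature matrix.

    The L2 strength is selected by marginal-likelihood maximization
    (iterated evidence updates, tolerance ``tol``, at most ``max_iter``
    iterations).  A constant target yields an intercept-only model.
    """
    X = getattr(features, "values", features)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ConfigError("features and target misaligned")
    if X.shape[0] < 2:
        raise ConfigError("need at least 2 rows to fit")
    if not np.isfinite(X).all():
        raise ConfigError("non-finite feature values")

    if np.all(y == y[0]):
        # degenerate target: heaviest possible shrinkage, intercept only
        return RidgeModel(
            weights=np.zeros(X.shape[1]),
            intercept=float(y[0]),
            l2_strength=math.inf,
            n_iter=0,
            converged=True,
        )

    br = BayesianRidge(max_iter=max_iter, tol=tol).fit(X, y)
    return RidgeModel(
        weights=br.coef_.copy(),
        intercept=float(br.intercept_),
        l2_strength=float(br.lambda_ / br.alpha_),
        n_iter=int(br.n_iter_),
        converged=bool(br.n_iter_ < max_iter),
    )


def predict_scores(model: RidgeModel, features: np.ndarray) -> np.ndarray:
    """Linear scores X @ w + b (unbounded reals; only ranks matter)."""
    X = getattr(features, "values", features)
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.weights.shape[0]:
        raise ConfigError(
            f"feature width {X.shape[1]} does not match model width {model.weights.shape[0]}"
        )
    return X @ model.weights + model.intercept


def nested_input_runner(
    images,
    attrs,
    oval: OvalSpec,
    plan=None,
    *,
    n_repeats: int = 20,
    n_folds: int = 5,
    backend: str = "pixel_pca",
    d_embed: int = 100,
    d_reduce: int | None = None,
    seed: int = 0,
    q: float = 0.05,
):
    """Run the CV protocol over the three nested input sets.

    Levels: (1) stated demographics; (2) + basic face metrics; (3) + reduced
    image embeddings.  Demographic-flagged attributes are the inputs of
    level 1 and are excluded from the prediction targets at every level.
    Returns an ordered dict level-name -> {variable: AUCResult}.
    """
    if not attrs.demographic.any():
        raise ConfigError("no attributes flagged as demographics")
    if plan is None:
        plan = make_cv_plan(attrs, n_repeats=n_repeats, n_folds=n_folds, seed=seed)
    targets = [n for n, d in zip(attrs.names, attrs.demographic) if not d]

    def embedding():
        return EmbeddingInput(
            make_backend(backend, d=d_embed, seed=seed), d_reduce=d_reduce
        )

    levels = {
        "demographics": lambda: StackedInput([DemographicsInput()]),
        "demographics+metrics": lambda: StackedInput(
            [DemographicsInput(), FaceMetricsInput(oval)]
        ),
        "demographics+metrics+embedding": lambda: StackedInput(
            [DemographicsInput(), FaceMetricsInput(oval), embedding()]
        ),
    }
    return {
        name: run_cv(images, attrs, plan, build(), targets=targets, q=q)
        for name, build in levels.items()
    }
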