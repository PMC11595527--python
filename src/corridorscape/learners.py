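"""Presence/background learners behind a common score contract.

Habitat suitability ensembles conventionally mix three model families: a
smooth additive model, a tree ensemble, and a maximum-entropy-style
model. Each family here is a thin scikit-learn pipeline exposing
``fit(X, y)`` and ``predict_score(X) -> scores in [0, 1]``; the ensemble
logic (gating, weighting, jackknife) lives in :mod:`corridorscape.sdm`
and treats fits as opaque.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler


class Learner(Protocol):
    learner_id: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner": ...

    def predict_score(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class SklearnLearner:
    """Wraps any sklearn classifier with predict_proba into the contract."""

    learner_id: str
    model: object

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnLearner":
        self.model.fit(X, y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        score = self.model.predict_proba(X)[:, 1]
        return np.clip(score, 0.0, 1.0)


def additive_learner(seed: int = 0, n_knots: int = 5) -> SklearnLearner:
    """Smooth additive model: per-feature spline basis + logistic link."""
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("splines", SplineTransformer(n_knots=n_knots, degree=3)),
            ("logit", LogisticRegression(max_iter=2000, C=10.0)),
        ]
    )
    return SklearnLearner("additive", pipe)


def forest_learner(seed: int = 0, n_estimators: int = 200) -> SklearnLearner:
    """Tree-ensemble model (random forest)."""
    rf = RandomForestClassifier(
        n_estimators=n_estimators, min_samples_leaf=3, random_state=seed, n_jobs=1
    )
    return SklearnLearner("forest", rf)


def maxent_learner(seed: int = 0) -> SklearnLearner:
    """Maximum-entropy-style model: regularized logistic regression on
    linear + quadratic + interaction features of the covariates."""
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("quad", PolynomialFeatures(degree=2, include_bias=False)),
            ("logit", LogisticRegression(max_iter=2000, C=1.0)),
        ]
    )
    return SklearnLearner("maxent", pipe)


def default_learners(seed: int = 0) -> list[SklearnLearner]:
    return [additive_learner(seed), forest_learner(seed), maxent_learner(seed)]
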