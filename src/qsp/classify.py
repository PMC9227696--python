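"""Bootstrap evaluation of a penalized multinomial classifier.

The evaluation protocol is the contribution here, not the optimizer: 100
stratified 70/30 train/test splits, a multinomial elastic-net logistic
regression (mixing parameter alpha, regularization strength chosen by
internal cross-validation on the training subset), and one-vs-rest
sensitivity/specificity per class aggregated across splits. A final model
fitted on all labeled samples reports its selected (nonzero-coefficient)
genes and classifies new samples.

The solver is a pluggable contract: anything with ``fit(X, y)``,
``predict(X)``, ``predict_proba(X)`` and a ``coef_`` matrix satisfies it.
The default wraps scikit-learn's saga elastic-net path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV

logger = logging.getLogger("qsp")

__all__ = [
    "ClassifierSpec",
    "ElasticNetMultinomial",
    "prepare_features",
    "bootstrap_evaluate",
    "fit_final_and_classify",
]


@dataclass
class ClassifierSpec:
    """Elastic-net multinomial classifier settings.

    alpha is the L1/L2 mixing parameter (1 = lasso); regularization
    strength is selected by ``cv_folds``-fold cross-validation over
    ``n_lambda`` logarithmically spaced strengths.
    """

    alpha: float = 0.95
    classes: list[str] = field(default_factory=list)
    cv_folds: int = 5
    n_lambda: int = 10
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


class ElasticNetMultinomial:
    """Default solver satisfying the classifier contract.

    Wraps a saga-solver multinomial logistic regression with elastic-net
    penalty; C is chosen by internal grid-search cross-validation.
    """

    def __init__(self, spec: ClassifierSpec, seed: int | None = None):
        self.spec = spec
        self.seed = seed
        self.model_: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ElasticNetMultinomial":
        spec = self.spec
        base = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=spec.alpha,
            max_iter=spec.max_iter,
            tol=1e-3,
            random_state=self.seed,
        )
        cs = np.logspace(-2, 2, spec.n_lambda)
        counts = np.bincount(pd.factorize(y)[0])
        folds = min(spec.cv_folds, int(counts.min()))
        if folds >= 2:
            search = GridSearchCV(base, {"C": cs}, cv=folds, n_jobs=1)
            search.fit(X, y)
            self.model_ = search.best_estimator_
        else:
            base.set_params(C=1.0)
            base.fit(X, y)
            self.model_ = base
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)

    @property
    def coef_(self) -> np.ndarray:
        return self.model_.coef_

    @property
    def classes_(self) -> np.ndarray:
        return self.model_.classes_


def prepare_features(
    patient: pd.DataFrame, newdata: pd.DataFrame, top_n: int = 7500
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variance-filter each matrix, intersect genes, standardize gene-wise.

    Both inputs are genes x samples. The variance filter keeps the top
    ``top_n`` genes of each matrix independently; only genes surviving in
    both are retained, and each matrix is standardized on its own samples.
    """
    def top_var(m: pd.DataFrame) -> pd.Index:
        v = m.var(axis=1, ddof=1)
        return v.sort_values(ascending=False, kind="mergesort").index[: min(top_n, len(v))]

    shared = top_var(patient).intersection(top_var(newdata))
    if len(shared) == 0:
        raise ValueError("no genes shared after variance filtering")

    def standardize(m: pd.DataFrame) -> pd.DataFrame:
        arr = m.loc[shared].to_numpy(dtype=float)
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        return pd.DataFrame((arr - mean) / sd, index=shared, columns=m.columns)

    return standardize(patient), standardize(newdata)


def _stratified_split(
    y: pd.Series, train_frac: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Per-class split; train size = round-half-up of train_frac * class size."""
    import math

    train, test = [], []
    for cls in sorted(y.unique()):
        members = list(y.index[y == cls])
        n_train = int(math.floor(train_frac * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def _rates(y_true: np.ndarray, y_pred: np.ndarray, classes: list) -> pd.DataFrame:
    rows = []
    for cls in classes:
        pos = y_true == cls
        tp = int(np.sum(pos & (y_pred == cls)))
        fn = int(np.sum(pos & (y_pred != cls)))
        tn = int(np.sum(~pos & (y_pred != cls)))
        fp = int(np.sum(~pos & (y_pred == cls)))
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows.append({"class": cls, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


@dataclass
class EvalResult:
    """Per-split and aggregate one-vs-rest classification rates."""

    per_set: pd.DataFrame  # columns: set, class, sensitivity, specificity
    summary: pd.DataFrame  # per class: mean/sd sensitivity and specificity

    def mean_sensitivity(self) -> pd.Series:
        return self.summary.set_index("class")["sensitivity_mean"]


def bootstrap_evaluate(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    n_sets: int = 100,
    train_frac: float = 0.7,
    seed: int | None = None,
    solver_factory=None,
) -> EvalResult:
    """Stratified 70/30 bootstrap evaluation of the classifier.

    ``X`` is genes x samples (already prepared); ``y`` maps sample ->
    class. For each of ``n_sets`` splits the classifier is fitted on the
    training subset and scored on the held-out subset; per-class
    sensitivity and specificity are aggregated as mean and SD over sets.
    """
    y = y.loc[X.columns]
    counts = y.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with < 2 samples: {small}")
    classes = sorted(y.unique())
    rng = np.random.default_rng(seed)
    if solver_factory is None:
        solver_factory = lambda s: ElasticNetMultinomial(spec, seed=s)
    per_set = []
    for b in range(n_sets):
        train, test = _stratified_split(y, train_frac, rng)
        clf = solver_factory(int(rng.integers(2**31)))
        clf.fit(X[train].T.to_numpy(), y.loc[train].to_numpy())
        pred = clf.predict(X[test].T.to_numpy())
        rates = _rates(y.loc[test].to_numpy(), np.asarray(pred), classes)
        rates.insert(0, "set", b)
        per_set.append(rates)
    per_set = pd.concat(per_set, ignore_index=True)
    summary = (
        per_set.groupby("class")
        .agg(
            sensitivity_mean=("sensitivity", "mean"),
            sensitivity_sd=("sensitivity", "std"),
            specificity_mean=("specificity", "mean"),
            specificity_sd=("specificity", "std"),
        )
        .reset_index()
    )
    return EvalResult(per_set=per_set, summary=summary)


def fit_final_and_classify(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    newX: pd.DataFrame,
    seed: int | None = None,
    solver_factory=None,
) -> tuple[list[str], pd.Series, pd.DataFrame]:
    """Fit on all labeled samples; report selected genes and classify new samples.

    ``newX`` must share ``X``'s gene rows exactly. Returns (selected
    feature list, predicted class per new sample, class probabilities).
    """
    if list(newX.index) != list(X.index):
        raise ValueError("new-sample gene set differs from the training gene set")
    y = y.loc[X.columns]
    if solver_factory is None:
        solver_factory = lambda s: ElasticNetMultinomial(spec, seed=s)
    clf = solver_factory(seed)
    clf.fit(X.T.to_numpy(), y.to_numpy())
    nonzero = np.any(np.abs(clf.coef_) > 0, axis=0)
    selected = [g for g, nz in zip(X.index, nonzero) if nz]
    proba = clf.predict_proba(newX.T.to_numpy())
    classes = list(clf.classes_)
    proba_df = pd.DataFrame(proba, index=newX.columns, columns=classes)
    pred = pd.Series(
        [classes[i] for i in np.argmax(proba, axis=1)], index=newX.columns, name="predicted"
    )
    return selected, pred, proba_df
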