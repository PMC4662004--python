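"""Imbalance-weighted maximum-margin screening classifiers.

Screening corpora are heavily skewed (roughly one relevant citation per nine
irrelevant ones), so each training instance is weighted by N / (2 * N_c),
where N_c is its class size: the total weight mass of the two classes is
then equal and the minority class is not swamped by the hinge loss.  The
quadratic program itself is delegated to libsvm via scikit-learn; the
contract here is the decision-function semantics (positive margin means
"relevant") with linear, RBF and polynomial kernels at solver defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .corpus import FeatureMatrix
from .errors import ValidationError

KERNELS = ("linear", "rbf", "poly")


@dataclass
class KernelSpec:
    """Kernel family and its (solver-default) shape parameters."""

    kind: str = "linear"
    gamma: float | str = "auto"  # "auto" = 1 / n_features
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self):
        if self.kind not in KERNELS:
            raise ValidationError(f"unknown kernel {self.kind!r}")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")


def compute_instance_weights(labels: np.ndarray) -> np.ndarray:
    """Class-balanced instance weights w_i = N / (2 * N_{class(i)}).

    Summed over either class the weights give N/2, so both classes carry the
    same penalty mass regardless of the imbalance ratio.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("instance weighting needs exactly two classes")
    n = len(y)
    per_class = {c: n / (2.0 * cnt) for c, cnt in zip(classes, counts)}
    return np.array([per_class[c] for c in y], dtype=float)


class ImbalanceWeightedSVC(BaseEstimator, ClassifierMixin):
    """Soft-margin SVM with class-balancing instance weights.

    Parameters mirror the libsvm defaults the screening experiments use: cost
    C=1, RBF/poly gamma = 1/n_features, polynomial degree 3.  The polynomial
    kernel is inhomogeneous (coef0=1): on simplex-valued topic features the
    homogeneous cubic has dynamic range ~1e-5 and its decision function
    collapses onto the bias term, so the lower-order terms are kept.
    ``balance_weights=False`` reduces to the plain unweighted trainer.

    Attributes
    ----------
    svc_ : sklearn.svm.SVC
        The fitted solver.
    classes_ : ndarray
        Sorted class labels; the decision function is positive toward
        ``classes_[1]`` (+1, "relevant").
    """

    def __init__(
        self,
        kernel: str = "linear",
        C: float = 1.0,
        gamma: float | str = "auto",
        degree: int = 3,
        coef0: float = 1.0,
        balance_weights: bool = True,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.balance_weights = balance_weights

    def fit(self, X, y, sample_weight: np.ndarray | None = None):
        KernelSpec(kind=self.kernel, gamma=self.gamma,
                   degree=self.degree, coef0=self.coef0)
        y = np.asarray(y)
        _check_finite(X)
        if sample_weight is None and self.balance_weights:
            sample_weight = compute_instance_weights(y)
        self.svc_ = SVC(
            kernel=self.kernel, C=self.C, gamma=self.gamma,
            degree=self.degree, coef0=self.coef0,
        )
        self.svc_.fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_dim(X)
        return self.svc_.decision_function(X)

    def predict(self, X) -> np.ndarray:
        """Labels by thresholding the margin at zero."""
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])

    def _check_dim(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature dimension {X.shape[1]} != {self.n_features_in_} at fit"
            )
        _check_finite(X)


def _check_finite(X):
    data = X.data if sp.issparse(X) else np.asarray(X)
    if not np.all(np.isfinite(data)):
        raise ValidationError("features contain non-finite values")


def train_classifier(
    features: FeatureMatrix,
    weights: np.ndarray | None = None,
    kernel: KernelSpec | str = "linear",
    cost: float = 1.0,
) -> ImbalanceWeightedSVC:
    """Train a weighted maximum-margin classifier on a feature matrix."""
    spec = KernelSpec(kind=kernel) if isinstance(kernel, str) else kernel
    clf = ImbalanceWeightedSVC(
        kernel=spec.kind, C=cost, gamma=spec.gamma,
        degree=spec.degree, coef0=spec.coef0,
    )
    clf.fit(features.X, features.y, sample_weight=weights)
    return clf


def decision_scores(
    model: ImbalanceWeightedSVC, features: FeatureMatrix
) -> np.ndarray:
    """Real-valued margins, positive toward the relevant class."""
    return model.decision_function(features.X)
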