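"""Per-timepoint linear decoding with probability calibration.

At a single time sample, trials form an ``n_trials x n_channels`` matrix.
A decoder is trained per sample under stratified k-fold cross-validation:

1. channels are z-scored with mean/SD estimated on the training fold only;
2. a linear max-margin classifier (hinge loss, regularization constant
   fixed at 1) is fit with per-trial sample weights that equalize the total
   contribution of the four design subclasses (LSGS, LDGS, LSGD, LDGD);
3. the decision values are passed through a Platt sigmoid fit on the same
   training fold, yielding a calibrated probability of class deviant;
4. performance on held-out trials is summarized by the ROC AUC with ties
   counted 1/2 (the Mann-Whitney convention), so AUC * n1 * n2 equals the
   Mann-Whitney U statistic computed on the same scores.

Class convention throughout: deviant = +1, standard = -1, so AUC > 0.5
means deviants receive higher probabilities and AUC < 0.5 indicates a
sign-reversed pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .epochs import ContrastSpec


@dataclass(frozen=True)
class FoldAssignment:
    """Cross-validation fold index per trial of a contrast."""

    k: int
    fold_index: np.ndarray  # (n_trials,) int, test-fold membership
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_index, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must contain at least one test trial")


def stratified_folds(contrast: ContrastSpec, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign trials to k stratified folds, preserving subclass proportions.

    Stratification is on the design subclass (not just the binary class) so
    each fold mirrors the LSGS/LDGS/LSGD/LDGD composition of the session.
    Deterministic given ``seed``.
    """
    subclass = np.asarray(contrast.subclass)
    classes, counts = np.unique(subclass.astype(str), return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(
                f"subclass {cls!r} has only {cnt} trials; need >= k={k} "
                f"for stratified {k}-fold cross-validation"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(contrast.n_trials, dtype=np.intp)
    dummy = np.zeros((contrast.n_trials, 1))
    for f, (_, test_idx) in enumerate(skf.split(dummy, subclass.astype(str))):
        fold_index[test_idx] = f
    return FoldAssignment(k=k, fold_index=fold_index, seed=seed)


def subclass_weights(subclasses: ContrastSpec | np.ndarray) -> np.ndarray:
    """Per-trial weights equalizing the total weight of each subclass.

    A trial in subclass ``s`` gets weight proportional to ``1 / count(s)``,
    scaled so the weights sum to the number of trials.
    """
    if isinstance(subclasses, ContrastSpec):
        subclasses = subclasses.subclass
    subclasses = np.asarray(subclasses).astype(str)
    if subclasses.size == 0:
        raise ValueError("no trials to weight")
    classes, inverse, counts = np.unique(
        subclasses, return_inverse=True, return_counts=True
    )
    w = 1.0 / counts[inverse]
    return w * (subclasses.size / w.sum())


@dataclass(frozen=True)
class Normalizer:
    """Per-channel z-scoring parameters estimated on training data."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def fit_normalizer(train_data: np.ndarray) -> Normalizer:
    """Estimate per-channel mean and SD from training trials.

    Channels with zero variance get SD 1, so a constant channel is mapped
    to all-zeros instead of raising a division error.
    """
    train_data = np.asarray(train_data, dtype=np.float64)
    if train_data.ndim != 2 or train_data.shape[0] < 2:
        raise ValueError("need a 2-D (trials x channels) array with >= 2 trials")
    mean = train_data.mean(axis=0)
    sd = train_data.std(axis=0)
    # constant channels (SD zero up to rounding) are mapped to ~0, not inf
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    sd = np.where(constant, 1.0, sd)
    return Normalizer(mean=mean, sd=sd)


def _platt_fit(
    decision_values: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    min_step: float = 1e-10,
    ridge: float = 1e-12,
) -> tuple[float, float]:
    """Fit Platt sigmoid coefficients (A, B) by penalized maximum likelihood.

    Models P(y=+1 | f) = 1 / (1 + exp(A f + B)) with the usual smoothed
    targets (N+ + 1)/(N+ + 2) and 1/(N- + 2), minimized by a damped Newton
    iteration with backtracking line search.  Deterministic.
    """
    f = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(y)
    n_pos = int((y > 0).sum())
    n_neg = f.size - n_pos
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y > 0, hi, lo)

    def objective(a: float, b: float) -> float:
        fab = a * f + b
        return float(
            np.sum(
                np.where(
                    fab >= 0,
                    t * fab + np.log1p(np.exp(-fab)),
                    (t - 1.0) * fab + np.log1p(np.exp(fab)),
                )
            )
        )

    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))
    fval = objective(A, B)
    for _ in range(max_iter):
        fab = A * f + B
        expm = np.exp(-np.abs(fab))
        p = np.where(fab >= 0, expm / (1.0 + expm), 1.0 / (1.0 + expm))
        pq = p * (1.0 - p)
        h11 = float(np.dot(f * f, pq)) + ridge
        h22 = float(np.sum(pq)) + ridge
        h21 = float(np.dot(f, pq))
        d = t - p
        g1 = float(np.dot(f, d))
        g2 = float(np.sum(d))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            new_a, new_b = A + step * dA, B + step * dB
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                A, B, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            break  # line search failed; accept current point
    return A, B


@dataclass(frozen=True)
class TimepointModel:
    """A trained decoder for one time sample.

    Holds the hyperplane (``weights``, ``intercept``) in z-scored channel
    space, the normalization parameters it was trained with, and the Platt
    sigmoid ``(platt_a, platt_b)`` mapping decision values to probabilities.
    """

    weights: np.ndarray
    intercept: float
    normalizer: Normalizer
    platt_a: float
    platt_b: float
    train_time: float
    regularization_constant: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.weights.size

    def decision_values(self, data: np.ndarray) -> np.ndarray:
        """Signed distance-like score for trials at one time sample."""
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] != self.n_channels:
            raise ValueError(
                f"expected (n_trials, {self.n_channels}) data, got {data.shape}"
            )
        return self.normalizer.transform(data) @ self.weights + self.intercept


def train_timepoint(
    train_data: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    time: float = 0.0,
    C: float = 1.0,
) -> TimepointModel:
    """Fit a calibrated linear decoder at one time sample.

    ``train_data`` is raw (un-normalized); z-scoring parameters are
    estimated here from the training trials only, so no information leaks
    from held-out data.  The classifier is a linear support vector machine
    (hinge loss, regularization constant ``C`` fixed at 1 by default) fit
    with the given per-trial weights; Platt calibration is then fit on the
    training decision values.
    """
    y = np.asarray(y)
    if not ((y > 0).any() and (y < 0).any()):
        raise ValueError("training set must contain both classes")
    norm = fit_normalizer(train_data)
    Xn = norm.transform(np.asarray(train_data, dtype=np.float64))
    svm = SVC(kernel="linear", C=C)
    with sklearn.config_context(assume_finite=True):
        svm.fit(Xn, y.astype(np.float64), sample_weight=weights)
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])
    f_train = Xn @ w + b
    a, pb = _platt_fit(f_train, y)
    return TimepointModel(
        weights=w,
        intercept=b,
        normalizer=norm,
        platt_a=a,
        platt_b=pb,
        train_time=float(time),
        regularization_constant=C,
    )


def predict_probability(model: TimepointModel, data: np.ndarray) -> np.ndarray:
    """Calibrated probability of class deviant for trials at one time sample.

    Probabilities lie in (0, 1) and increase monotonically with the decision
    value (the Platt slope is negative whenever the decision values separate
    the training classes in the conventional direction).
    """
    f = model.decision_values(data)
    fab = model.platt_a * f + model.platt_b
    expm = np.exp(-np.abs(fab))
    return np.where(fab >= 0, expm / (1.0 + expm), 1.0 / (1.0 + expm))


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve with ties counted 1/2.

    Equals the probability that a uniformly drawn (deviant, standard) pair
    is ranked correctly, and satisfies ``auc * n1 * n2 == U`` for the
    Mann-Whitney U statistic of the same scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    pos = y > 0
    n1 = int(pos.sum())
    n2 = scores.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("auc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))
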