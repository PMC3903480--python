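"""Temporal generalization: train at time t, test at every time t'.

For each cross-validation fold and each training sample t, a decoder is fit
on the training trials at t and applied to the held-out trials at every
test sample t'.  Because folds are fixed before training, a trial used to
train at t is never among the trials scored at t' — the hygiene that keeps
auto-correlated noise from masquerading as generalization.  Held-out
probabilities are pooled across folds (each trial is predicted exactly once
per matrix cell) and one AUC is computed per (t, t') cell, giving the
train-time x test-time generalization matrix.

Reading the matrix: decoding confined to the diagonal means each instant
has its own short-lived code (serial dynamics); a filled square means one
code is maintained over the whole window (sustained dynamics); cells below
0.5 mean the discriminative pattern has flipped sign between t and t'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import (
    FoldAssignment,
    auc,
    predict_probability,
    stratified_folds,
    subclass_weights,
    train_timepoint,
)
from .epochs import ContrastSpec, EpochsSet


@dataclass
class TGMatrix:
    """Train-time x test-time AUC matrix for one subject.

    ``probabilities[i, ti, tj]`` is the pooled held-out probability of trial
    ``i`` under the decoder trained at ``train_times[ti]`` and tested at
    ``test_times[tj]`` (kept when ``store_probabilities``), enabling
    within-subject trial-level statistics per cell.
    """

    train_times: np.ndarray
    test_times: np.ndarray
    auc: np.ndarray
    subject_id: str = ""
    folds: FoldAssignment | None = None
    y: np.ndarray | None = None
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=np.float64)
        if self.auc.shape != (len(self.train_times), len(self.test_times)):
            raise ValueError("auc shape does not match time grids")
        if ((self.auc < 0) | (self.auc > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (train_time, test_time, auc) table."""
        tr, te = np.meshgrid(self.train_times, self.test_times, indexing="ij")
        return pd.DataFrame(
            {
                "train_time": tr.ravel(),
                "test_time": te.ravel(),
                "auc": self.auc.ravel(),
            }
        )


def _run(
    epochs: EpochsSet,
    contrast: ContrastSpec,
    folds: FoldAssignment,
    diagonal_only: bool,
    store_probabilities: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared engine for full-matrix and diagonal-only decoding.

    Returns (probabilities, y).  ``probabilities`` has shape
    ``(n_trials, T, T)`` for the full matrix and ``(n_trials, T)`` for the
    diagonal; entries are pooled held-out predictions.  The diagonal-only
    path performs the identical training calls and the identical per-slice
    prediction calls as the matrix diagonal, so the two agree bit-for-bit.
    """
    X = epochs.data[contrast.trial_indices]
    y = contrast.y
    times = epochs.times
    n, _, T = X.shape
    if diagonal_only:
        probs = np.full((n, T), np.nan)
    else:
        probs = np.full((n, T, T), np.nan)
    for f in range(folds.k):
        test = folds.fold_index == f
        train = ~test
        w_train = subclass_weights(contrast.subclass[train])
        y_train = y[train]
        X_train = X[train]
        X_test = X[test]
        for ti in range(T):
            model = train_timepoint(
                X_train[:, :, ti], y_train, w_train, time=times[ti]
            )
            if diagonal_only:
                probs[test, ti] = predict_probability(model, X_test[:, :, ti])
            else:
                for tj in range(T):
                    probs[test, ti, tj] = predict_probability(
                        model, X_test[:, :, tj]
                    )
    return probs, y


def run_tgm(
    epochs: EpochsSet,
    contrast: ContrastSpec,
    folds: FoldAssignment | None = None,
    k: int = 10,
    seed: int = 0,
    store_probabilities: bool = True,
) -> TGMatrix:
    """Compute the temporal generalization matrix for one subject.

    ``folds`` defaults to :func:`stratified_folds` with the given ``k`` and
    ``seed``.  The returned matrix has one AUC per (train, test) cell,
    computed from the pooled held-out probabilities of all trials.
    """
    if folds is None:
        folds = stratified_folds(contrast, k=k, seed=seed)
    probs, y = _run(epochs, contrast, folds, diagonal_only=False,
                    store_probabilities=store_probabilities)
    T = probs.shape[1]
    mat = np.empty((T, T))
    for ti in range(T):
        for tj in range(T):
            mat[ti, tj] = auc(probs[:, ti, tj], y)
    return TGMatrix(
        train_times=epochs.times.copy(),
        test_times=epochs.times.copy(),
        auc=mat,
        subject_id=epochs.subject_id,
        folds=folds,
        y=y.copy(),
        probabilities=probs if store_probabilities else None,
    )


def decode_diagonal(
    epochs: EpochsSet,
    contrast: ContrastSpec,
    folds: FoldAssignment | None = None,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Train and test at the same sample, over all samples.

    With the same folds and seed this equals ``diagonal(run_tgm(...))``
    exactly, because both paths issue identical training and prediction
    calls.
    """
    if folds is None:
        folds = stratified_folds(contrast, k=k, seed=seed)
    probs, y = _run(epochs, contrast, folds, diagonal_only=True,
                    store_probabilities=False)
    return np.array([auc(probs[:, ti], y) for ti in range(probs.shape[1])])


def diagonal(tgm: TGMatrix) -> np.ndarray:
    """The diagonal-decoding curve of a square generalization matrix."""
    if len(tgm.train_times) != len(tgm.test_times):
        raise ValueError("generalization matrix is not square")
    return np.diagonal(tgm.auc).copy()


@dataclass(frozen=True)
class DurationSummary:
    """Generalization durations per training time, in milliseconds."""

    train_times: np.ndarray  # training times entering the mean
    durations_ms: np.ndarray  # significant generalization span per train time
    mean_ms: float


def generalization_duration(
    mask: np.ndarray,
    times: np.ndarray,
    sample_rate: float,
    window: tuple[float, float] | None = None,
) -> DurationSummary:
    """Mean time span over which decoders generalize significantly.

    ``mask`` is a boolean significance matrix (train x test), e.g. an
    FDR-corrected map; a stack ``(n_subjects, T, T)`` yields per-subject
    summaries whose means are averaged across subjects.  For each training
    time inside the window whose diagonal cell is significant, the duration
    is the count of significant test samples inside the window times
    ``1000/sample_rate`` ms; the summary mean is taken over those
    diagonal-significant training times.  ``window=None`` applies the
    data-driven rule: the window is the set of samples whose diagonal cell
    is significant (the analogue of restricting to the span where diagonal
    decoding performs above chance); a fixed ``(t_start, t_end)`` window in
    seconds can be given instead.
    """
    mask = np.asarray(mask, dtype=bool)
    times = np.asarray(times, dtype=np.float64)
    if mask.ndim == 3:
        per_subject = [
            generalization_duration(m, times, sample_rate, window) for m in mask
        ]
        means = np.array([s.mean_ms for s in per_subject])
        return DurationSummary(
            train_times=times.copy(),
            durations_ms=means,
            mean_ms=float(means.mean()),
        )
    if mask.shape[0] != mask.shape[1] or mask.shape[0] != times.size:
        raise ValueError("mask must be square and match the time grid")
    diag = np.diagonal(mask)
    if window is None:
        in_window = diag.copy()
    else:
        t0, t1 = window
        in_window = (times >= t0) & (times < t1)
        if not in_window.any():
            raise ValueError("duration window contains no samples")
    ms_per_sample = 1000.0 / sample_rate
    qualifying = in_window & diag
    durations = mask[:, in_window].sum(axis=1) * ms_per_sample
    if not qualifying.any():
        return DurationSummary(
            train_times=times[qualifying],
            durations_ms=durations[qualifying],
            mean_ms=0.0,
        )
    return DurationSummary(
        train_times=times[qualifying],
        durations_ms=durations[qualifying],
        mean_ms=float(durations[qualifying].mean()),
    )


def diag_offdiag_contrast(
    tgm_stack: np.ndarray | list[TGMatrix],
    times: np.ndarray | None = None,
    train_time: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Paired per-subject differences AUC(t, t') - AUC(t', t').

    Compares the generalization row of the decoder trained at ``train_time``
    against the diagonal decoders at every test time, per subject, ready for
    a paired group test.  Returns the difference array ``(n_subjects,
    n_test_times)`` and the subject count.
    """
    if isinstance(tgm_stack, (list, tuple)):
        if times is None:
            times = tgm_stack[0].train_times
        stack = np.stack([t.auc for t in tgm_stack])
    else:
        stack = np.asarray(tgm_stack)
        if times is None:
            raise ValueError("times required when passing a plain array stack")
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 subjects")
    times = np.asarray(times, dtype=np.float64)
    matches = np.flatnonzero(np.isclose(times, train_time, atol=1e-9))
    if matches.size == 0:
        raise ValueError(f"train_time {train_time} not on the time grid")
    ti = int(matches[0])
    diffs = stack[:, ti, :] - np.diagonal(stack, axis1=1, axis2=2)
    return diffs, stack.shape[0]
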