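"""Nonparametric inference for decoding outputs.

Within a subject, trials are the random variable: the calibrated
probabilities of the two classes are compared with a Mann-Whitney U test,
whose statistic is tied to the decoder's AUC by ``U = AUC * n1 * n2``
(shared midrank tie convention).  Across subjects, per-subject AUCs (or
paired differences) are tested against chance with the Wilcoxon signed-rank
test, enumerated exactly for small cohorts.  Two-sided p-values are the
default because below-chance decoding is meaningful here: a decoder that
generalizes with AUC < 0.5 has found a sign-flipped pattern, not noise.
Cell-wise maps over a generalization matrix are corrected with the
Benjamini-Hochberg false discovery rate procedure, treating all t x t'
cells of a map as one family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    n: int
    direction: int  # sign of the observed effect (+1, -1, or 0)
    method: str = ""


def within_subject_test(
    probabilities: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test of deviant vs standard decoder outputs.

    Trials are the random variable.  The returned statistic is the U of the
    deviant class, so ``U / (n1 * n2)`` equals the AUC of the same scores.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(y)
    pos = probabilities[y > 0]
    neg = probabilities[y <= 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    res = sps.mannwhitneyu(pos, neg, alternative=alternative)
    auc = res.statistic / (pos.size * neg.size)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=pos.size + neg.size,
        direction=int(np.sign(auc - 0.5)),
        method="mann-whitney",
    )


def within_subject_pmap(probabilities: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-cell Mann-Whitney p-values over a probability cube.

    ``probabilities`` has shape ``(n_trials, T, T)`` (pooled held-out
    predictions per generalization cell); returns a ``(T, T)`` two-sided
    p-map using the normal approximation with tie correction, appropriate
    for the trial counts this test is used at.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(y)
    res = sps.mannwhitneyu(
        probabilities[y > 0],
        probabilities[y <= 0],
        alternative="two-sided",
        method="asymptotic",
        axis=0,
    )
    return np.asarray(res.pvalue)


@lru_cache(maxsize=256)
def _signed_rank_null_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Sign-flip null counts of the doubled signed-rank sum 2*W+.

    ``doubled_ranks`` are the (midrank) ranks of |d| times two, so they are
    integers even under ties.  ``counts[w]`` is the number of the 2^n sign
    assignments whose positive-rank sum equals ``w / 2``.  Conditioning on
    the observed midranks gives the exact permutation (sign-flip) null even
    when absolute differences tie.
    """
    counts = np.zeros(sum(doubled_ranks) + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def _exact_signed_rank_p(
    w_plus: float, ranks: np.ndarray, alternative: str
) -> float:
    doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
    counts = _signed_rank_null_counts(doubled)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    w = int(round(2 * w_plus))
    p_le = cdf[w]
    p_ge = 1.0 - (cdf[w - 1] if w >= 1 else 0.0)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def across_subject_test(
    per_subject_values: np.ndarray,
    null_value: float = 0.5,
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon signed-rank test of per-subject values against a null value.

    Zero differences are dropped; for n <= 25 the sign-flip null
    distribution is enumerated exactly, conditioning on the observed
    midranks when absolute differences tie, otherwise the normal
    approximation with continuity correction is used.
    If every difference is zero the test is undefined and p = 1 is returned
    with a warning.
    """
    values = np.asarray(per_subject_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    d = values - null_value
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all differences equal the null value; p = 1", UserWarning)
        return TestResult(
            statistic=0.0, p_value=1.0, n=0, direction=0, method="wilcoxon"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= 25:
        p = _exact_signed_rank_p(w_plus, ranks, alternative)
        method = "wilcoxon-exact"
    else:
        res = sps.wilcoxon(
            d, alternative=alternative, method="approx", correction=True
        )
        p = float(res.pvalue)
        method = "wilcoxon-approx"
    return TestResult(
        statistic=w_plus,
        p_value=p,
        n=int(d.size),
        direction=int(np.sign(np.median(d))) if d.size else 0,
        method=method,
    )


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR correction.

    Rejects all hypotheses with p <= p_(k) where k is the largest i with
    p_(i) <= i*q/m.  Returns (mask, threshold); the threshold is 0 when
    nothing is rejected.  An empty input yields an empty mask.
    """
    p = np.asarray(p_values, dtype=np.float64)
    shape = p.shape
    p = p.ravel()
    m = p.size
    if m == 0:
        return np.zeros(shape, dtype=bool), 0.0
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= q * np.arange(1, m + 1) / m
    if not below.any():
        return np.zeros(shape, dtype=bool), 0.0
    threshold = float(sorted_p[np.flatnonzero(below)[-1]])
    return (p <= threshold).reshape(shape), threshold


@dataclass
class StatMap:
    """Group-level statistics over a stack of generalization matrices."""

    p: np.ndarray  # per-cell two-sided p vs chance
    mask: np.ndarray  # per-cell FDR significance
    threshold: float  # data-dependent BH threshold (0 if nothing rejected)
    q: float
    mean: np.ndarray  # group mean AUC per cell
    sem: np.ndarray  # standard error of the mean across subjects
    n_subjects: int


def _wilcoxon_pmap(diffs: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided signed-rank p per column of ``diffs``.

    ``diffs`` is ``(n_subjects, n_cells)``.  Columns with zeros or tied
    absolute differences fall back to :func:`across_subject_test` so every
    cell follows the same convention.
    """
    n, n_cells = diffs.shape
    absd = np.abs(diffs)
    sorted_abs = np.sort(absd, axis=0)
    clean = (absd > 0).all(axis=0) & (np.diff(sorted_abs, axis=0) > 0).all(axis=0)
    p = np.empty(n_cells)
    if clean.any():
        ranks = sps.rankdata(absd[:, clean], axis=0)
        w2 = np.rint(2 * np.sum(ranks * (diffs[:, clean] > 0), axis=0)).astype(int)
        counts = _signed_rank_null_counts(tuple(range(2, 2 * n + 1, 2)))
        cdf = np.cumsum(counts) / counts.sum()
        p_le = cdf[w2]
        p_ge = 1.0 - np.where(w2 >= 1, cdf[w2 - 1], 0.0)
        p[clean] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    for j in np.flatnonzero(~clean):
        p[j] = across_subject_test(diffs[:, j], null_value=0.0).p_value
    return p


def group_statmap(
    tgm_stack: np.ndarray | list,
    q: float = 0.05,
    chance: float = 0.5,
) -> StatMap:
    """Across-subject inference on a stack of generalization matrices.

    Each cell's per-subject AUCs are tested against chance with the exact
    two-sided Wilcoxon signed-rank test; the resulting p-map is corrected
    with Benjamini-Hochberg over all cells as one family.
    """
    if isinstance(tgm_stack, (list, tuple)):
        stack = np.stack([getattr(t, "auc", t) for t in tgm_stack])
    else:
        stack = np.asarray(tgm_stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected a (n_subjects, T, T) stack")
    n_subjects = stack.shape[0]
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for group statistics")
    cells = stack.reshape(n_subjects, -1)
    p = _wilcoxon_pmap(cells - chance).reshape(stack.shape[1:])
    mask, threshold = fdr_correct(p, q=q)
    return StatMap(
        p=p,
        mask=mask,
        threshold=threshold,
        q=q,
        mean=stack.mean(axis=0),
        sem=stack.std(axis=0, ddof=1) / np.sqrt(n_subjects),
        n_subjects=n_subjects,
    )


def anti_generalization_contrast(
    tgm_stack: np.ndarray | list,
    times: np.ndarray,
    t: float,
    t_prime: float,
) -> TestResult:
    """Is a below-chance generalization a full or partial pattern reversal?

    Compares, per subject, the diagonal performance AUC(t, t) with the
    anti-generalization performance 1 - AUC(t, t') using a paired Wilcoxon
    test.  A significant positive direction means the diagonal beats the
    reversed generalization: the flip is only partial.
    """
    if isinstance(tgm_stack, (list, tuple)):
        stack = np.stack([getattr(s, "auc", s) for s in tgm_stack])
    else:
        stack = np.asarray(tgm_stack, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    it = np.flatnonzero(np.isclose(times, t, atol=1e-9))
    itp = np.flatnonzero(np.isclose(times, t_prime, atol=1e-9))
    if it.size == 0 or itp.size == 0:
        raise ValueError("t and t_prime must lie on the time grid")
    diag_perf = stack[:, it[0], it[0]]
    anti_perf = 1.0 - stack[:, it[0], itp[0]]
    return across_subject_test(diag_perf - anti_perf, null_value=0.0)
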