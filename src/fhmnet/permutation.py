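"""Non-parametric permutation tests with multiple-comparison correction.

Two family-wise error control strategies for comparing two groups of
neural maps:

* pixel-based (2-D maps, e.g. time-frequency modulation tiles): the null
  distributions collect the most extreme (minimum and maximum) values of
  the group-difference map over label permutations; observed pixels below
  the 2.5th percentile of the minima or above the 97.5th percentile of
  the maxima are significant (2.5% per tail);
* cluster-based (1-D traces, e.g. VEPs or band-power time courses): each
  permutation is thresholded pointwise at an uncorrected alpha and the
  maximal run length of consecutive significant points forms the null;
  observed clusters longer than its 97.5th percentile are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PermutationResult", "Cluster", "pixel_based_test",
           "cluster_based_test"]


@dataclass(frozen=True)
class Cluster:
    start: int
    end: int  # exclusive
    length: int
    p_value: float


@dataclass
class PermutationResult:
    observed: np.ndarray  # group difference (A - B) map or pointwise stat
    null_extremes: np.ndarray
    thresholds: tuple
    sig_mask: np.ndarray
    clusters: list = field(default_factory=list)


def _runs(mask: np.ndarray):
    """(start, end) pairs of runs of True."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def max_run_length(mask: np.ndarray) -> int:
    runs = _runs(mask)
    return max((e - s for s, e in runs), default=0)


def pixel_based_test(group_a: np.ndarray, group_b: np.ndarray,
                     n_perm: int = 1000, seed=0) -> PermutationResult:
    """Pixel-based permutation test on two groups of equally shaped maps.

    group_a/group_b: (n_subjects, *map_shape).  The observed statistic is
    the difference of group means; per permutation of the group labels the
    minimum and maximum of the permuted difference map are recorded, and
    the 2.5th / 97.5th percentiles of this pooled extremes distribution
    form the two-tailed corrected thresholds.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("map dimensions must match")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    observed = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    extremes = np.empty((n_perm, 2))
    for i in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        d = pooled[idx[:na]].mean(axis=0) - pooled[idx[na:]].mean(axis=0)
        extremes[i] = (d.min(), d.max())
    # two-tailed control: lower threshold from the minima distribution,
    # upper from the maxima distribution (2.5% per tail)
    lo = float(np.percentile(extremes[:, 0], 2.5))
    hi = float(np.percentile(extremes[:, 1], 97.5))
    sig = (observed < lo) | (observed > hi)
    return PermutationResult(observed=observed, null_extremes=extremes,
                             thresholds=(lo, hi), sig_mask=sig)


def _pointwise_t_sig(a, b, alpha):
    t, p = stats.ttest_ind(a, b, axis=0)
    return p < alpha


def cluster_based_test(group_a: np.ndarray, group_b: np.ndarray,
                       n_perm: int = 1000, alpha_unc: float = 0.05,
                       seed=0) -> PermutationResult:
    """Cluster-length permutation test on two groups of 1-D traces.

    The pointwise statistic is a two-sample t-test per time point.  Each
    permutation shuffles the trial labels, thresholds the pointwise
    p-values at ``alpha_unc`` and retains the maximal run length of
    consecutive significant points; observed runs longer than the 97.5th
    percentile of this null are significant.  (The lower tail of the
    run-length null is vacuous for run lengths and is not used.)
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("trace lengths must match")
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    rng = np.random.default_rng(seed)
    null_len = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        sig = _pointwise_t_sig(pooled[idx[:na]], pooled[idx[na:]], alpha_unc)
        null_len[i] = max_run_length(sig)
    thresh = float(np.percentile(null_len, 97.5))
    obs_sig = _pointwise_t_sig(a, b, alpha_unc)
    sig_mask = np.zeros_like(obs_sig)
    clusters = []
    for s, e in _runs(obs_sig):
        length = e - s
        p = (1.0 + np.sum(null_len >= length)) / (1.0 + n_perm)
        if length > thresh:
            sig_mask[s:e] = True
        clusters.append(Cluster(start=int(s), end=int(e),
                                length=int(length), p_value=float(p)))
    t, _ = stats.ttest_ind(a, b, axis=0)
    return PermutationResult(observed=t, null_extremes=null_len,
                             thresholds=(np.nan, thresh), sig_mask=sig_mask,
                             clusters=clusters)
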