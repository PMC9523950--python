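"""Mutual information between stimulus contrast and neural responses.

Plug-in Shannon MI on responses discretized into seven equi-populated
bins, the Panzeri-Treves analytic correction for the limited-sampling
upward bias, and bootstrap significance (stimulus/response shuffling)
with Bonferroni or extreme-pixel multiple-comparison correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIEstimate",
    "equipopulated_bins",
    "mutual_information",
    "joint_table",
    "panzeri_treves_correct",
    "mi_corrected",
    "bootstrap_significance",
]

N_BINS_DEFAULT = 7
N_BOOT_DEFAULT = 500


@dataclass
class MIEstimate:
    mi: float  # plug-in, bits
    mi_corrected: float  # bias-corrected, bits
    n_bins: int
    boot_null: np.ndarray = field(default_factory=lambda: np.array([]))
    p_value: float = np.nan
    significant: bool = False


def equipopulated_bins(responses, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Quantile-based discretization into (up to) n_bins equal-count bins.

    Returns integer labels in [0, n_bins).  With heavy ties several
    quantile edges may coincide; the effective number of bins then drops
    and a warning is issued.
    """
    r = np.asarray(responses, dtype=float)
    if r.size < n_bins:
        raise ValueError("need at least n_bins responses")
    edges = np.quantile(r, np.linspace(0, 1, n_bins + 1)[1:-1])
    labels = np.searchsorted(edges, r, side="right")
    if np.unique(labels).size < n_bins:
        warnings.warn("ties reduced the effective number of bins",
                      RuntimeWarning)
    return labels


def joint_table(stimuli, responses) -> np.ndarray:
    """Joint count table, stimuli on rows, response bins on columns."""
    s = np.unique(stimuli, return_inverse=True)[1]
    r = np.unique(responses, return_inverse=True)[1]
    table = np.zeros((s.max() + 1, r.max() + 1), dtype=np.int64)
    np.add.at(table, (s, r), 1)
    return table


def mutual_information(stimuli, responses) -> float:
    """Plug-in Shannon mutual information [bits] from the joint histogram."""
    stimuli = np.asarray(stimuli)
    responses = np.asarray(responses)
    if stimuli.size != responses.size:
        raise ValueError("stimuli and responses must be paired")
    if np.unique(stimuli).size < 2:
        warnings.warn("single stimulus class: MI is 0", RuntimeWarning)
        return 0.0
    table = joint_table(stimuli, responses)
    return _mi_from_table(table)


def _mi_from_table(table: np.ndarray) -> float:
    n = table.sum()
    p = table / n
    ps = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (ps @ pr)[nz])))


def _bayes_bin_count(row: np.ndarray) -> float:
    """Estimated number of response bins with nonzero true probability.

    Naively this is the number of occupied bins; when unoccupied bins
    exist, the estimate R solves  R_obs = R * (1 - (1 - 1/R)^N)  (the
    expected occupancy of R equiprobable bins after N draws), clipped to
    the total number of available bins.
    """
    n = row.sum()
    r_obs = int((row > 0).sum())
    r_max = row.size
    if n == 0 or r_obs == 0:
        return 0.0
    if r_obs == r_max:
        return float(r_obs)
    best, best_err = float(r_obs), np.inf
    for r in np.linspace(r_obs, r_max, 50):
        expected = r * (1.0 - (1.0 - 1.0 / r) ** n)
        err = abs(expected - r_obs)
        if err < best_err:
            best, best_err = r, err
    return float(best)


def panzeri_treves_correct(mi: float, table: np.ndarray) -> float:
    """Subtract the Panzeri-Treves limited-sampling bias estimate.

    bias = [ sum_s (R_s - 1) - (R - 1) ] / (2 N ln 2), with R_s the
    estimated number of effectively occupied response bins for stimulus s
    and R the same for the pooled responses.  The bias scales as 1/N and
    vanishes in the large-sample limit.
    """
    table = np.asarray(table)
    n = table.sum()
    if n == 0:
        return mi
    r_s = sum(_bayes_bin_count(row) - 1 for row in table if row.sum() > 0)
    r_tot = _bayes_bin_count(table.sum(axis=0)) - 1
    bias = (r_s - r_tot) / (2.0 * n * np.log(2.0))
    # near-deterministic tables can make the counting estimate negative;
    # the limited-sampling bias of plug-in MI is never downward, so the
    # correction is clamped at zero from below
    return mi - max(bias, 0.0)


def mi_corrected(stimuli, responses, n_bins: int = N_BINS_DEFAULT,
                 discretize: bool = True) -> MIEstimate:
    """Bias-corrected MI of (stimulus, scalar response) pairs."""
    if discretize:
        responses = equipopulated_bins(responses, n_bins)
    mi = mutual_information(stimuli, responses)
    table = joint_table(stimuli, responses)
    return MIEstimate(mi=mi, mi_corrected=panzeri_treves_correct(mi, table),
                      n_bins=n_bins)


def _shuffled_mi(stimuli, binned, rng) -> float:
    perm = rng.permutation(len(binned))
    mi = mutual_information(stimuli, binned[perm])
    return panzeri_treves_correct(mi, joint_table(stimuli, binned[perm]))


def bootstrap_significance(stimuli, response_map,
                           n_iter: int = N_BOOT_DEFAULT,
                           alpha: float = 0.05,
                           correction: str = "bonferroni",
                           n_bins: int = N_BINS_DEFAULT,
                           seed=0) -> list[MIEstimate]:
    """Pointwise bias-corrected MI with a shuffle null and FWE correction.

    ``response_map`` has one row per trial and one column per map element
    (time point for MUA-style maps, flattened time-frequency tile for
    scalogram maps); each column is binned independently.  The null
    distribution is built by randomly re-pairing stimuli and responses
    (``n_iter`` shuffles); p = (1 + #null >= observed) / (1 + n_iter).

    ``bonferroni`` tests each element at alpha / n_elements.
    ``extreme_pixel`` compares each observed value against the
    (1 - alpha) quantile of the per-iteration *maximum* corrected MI
    across elements, controlling the family-wise error over the map.
    """
    if n_iter < 100:
        raise ValueError("need at least 100 shuffle iterations")
    if correction not in ("bonferroni", "extreme_pixel"):
        raise ValueError("unknown correction")
    stimuli = np.asarray(stimuli)
    resp = np.atleast_2d(np.asarray(response_map, dtype=float))
    if resp.shape[0] != stimuli.size:
        resp = resp.T
    n_el = resp.shape[1]
    rng = np.random.default_rng(seed)
    binned = [equipopulated_bins(resp[:, j], n_bins) for j in range(n_el)]
    observed = []
    for j in range(n_el):
        mi = mutual_information(stimuli, binned[j])
        observed.append(panzeri_treves_correct(
            mi, joint_table(stimuli, binned[j])))
    null = np.empty((n_iter, n_el))
    for it in range(n_iter):
        perm = rng.permutation(stimuli.size)
        for j in range(n_el):
            b = binned[j][perm]
            null[it, j] = panzeri_treves_correct(
                mutual_information(stimuli, b), joint_table(stimuli, b))
    out = []
    if correction == "extreme_pixel":
        max_null = null.max(axis=1)
        thresh = np.quantile(max_null, 1.0 - alpha)
    for j in range(n_el):
        p = (1.0 + np.sum(null[:, j] >= observed[j])) / (1.0 + n_iter)
        if correction == "bonferroni":
            sig = p <= alpha / n_el
        else:
            sig = observed[j] > thresh
        mi_plug = mutual_information(stimuli, binned[j])
        out.append(MIEstimate(mi=mi_plug, mi_corrected=observed[j],
                              n_bins=n_bins, boot_null=null[:, j],
                              p_value=p, significant=bool(sig)))
    return out
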