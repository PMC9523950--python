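"""Model-level statistics: spectral modulation, I/E ratios, contrast gain.

These operate on simulation outputs (LFP proxy traces, per-pathway current
sums, population rates) and implement the quantities used to compare the
wild-type and FHM1 networks: the relative PSD modulation with respect to
the pre-stimulus baseline, the inhibitory-over-excitatory current ratio
(with and without the thalamic terms), firing-rate modulation, the linear
contrast-gain slope with a bootstrap slope-ratio, the high/low broad-gamma
split of the modulation spectrum, and a reduced chi-square agreement score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpectralModulation",
    "IERatioResult",
    "GammaBandSplit",
    "LOW_BB_BAND",
    "HIGH_BB_BAND",
    "psd_welch",
    "psd_modulation",
    "ie_ratio",
    "rate_modulation",
    "contrast_gain_slopes",
    "gamma_bb_ratio",
    "reduced_chi_square",
]

#: beta / low-gamma broad band [Hz]
LOW_BB_BAND = (12.0, 40.0)
#: high-gamma broad band [Hz]
HIGH_BB_BAND = (70.0, 100.0)


@dataclass
class SpectralModulation:
    freqs: np.ndarray
    mod: np.ndarray  # dimensionless, (PSD_K - PSD_pre) / PSD_pre
    K: object = None


@dataclass(frozen=True)
class IERatioResult:
    ie_total: float
    ie_recurrent: float
    K: object = None


@dataclass(frozen=True)
class GammaBandSplit:
    low_bb: float
    high_bb: float
    ratio: float
    #: True when the low-band average is non-positive and the signed ratio
    #: is therefore not a plain magnitude ratio
    flagged: bool = False


def psd_welch(x: np.ndarray, fs: float, segment_ms: float = 1000.0,
              overlap: float = 0.5):
    """Welch PSD with 1000 ms Hann segments and 50% overlap.

    The input is expected to be z-scored (the spectral pipeline works on
    normalized traces so modulations compare spectral shape, not gain).
    Returns (freqs [Hz], psd).
    """
    nperseg = int(round(segment_ms * 1e-3 * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    return signal.welch(x, fs=fs, nperseg=nperseg,
                        noverlap=int(nperseg * overlap))


def zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def psd_modulation(psd_K, psd_pre, freqs=None, K=None) -> SpectralModulation:
    """Elementwise spectral modulation (PSD_K - PSD_pre) / PSD_pre.

    Bins with zero pre-stimulus power are masked (NaN) with a warning.
    """
    psd_K = np.asarray(psd_K, dtype=float)
    psd_pre = np.asarray(psd_pre, dtype=float)
    if psd_K.shape != psd_pre.shape:
        raise ValueError("PSDs must share a frequency grid")
    mod = np.full_like(psd_K, np.nan)
    ok = psd_pre > 0
    if not ok.all():
        warnings.warn("zero pre-stimulus PSD bins masked", RuntimeWarning)
    mod[ok] = (psd_K[ok] - psd_pre[ok]) / psd_pre[ok]
    if freqs is None:
        freqs = np.arange(psd_K.size, dtype=float)
    return SpectralModulation(freqs=np.asarray(freqs, dtype=float), mod=mod, K=K)


def ie_ratio(currents: dict[str, np.ndarray], mode: str = "total",
             K=None) -> IERatioResult:
    """Inhibitory over excitatory time-summed |current| onto excitatory cells.

    ``recurrent``:  sum|I_GABA| / sum|I_AMPA,rec|.
    ``total``:      sum|I_GABA| / sum(|I_AMPA,rec| + |I_thal_S| + |I_thal_NB|).

    A ratio above 1 (or growing) marks a network state shifted towards
    inhibition; the FHM1 alterations shift the total ratio up at every
    contrast.
    """
    if mode not in ("total", "recurrent"):
        raise ValueError("mode must be 'total' or 'recurrent'")
    gaba = float(np.sum(currents["gaba"]))
    rec = float(np.sum(currents["ampa_rec"]))
    tot = rec + float(np.sum(currents["thal_s"])) + float(np.sum(currents["thal_nb"]))
    if rec <= 0 or tot <= 0:
        raise ZeroDivisionError("no excitatory current recorded; ratio undefined")
    return IERatioResult(ie_total=gaba / tot, ie_recurrent=gaba / rec, K=K)


def rate_modulation(rate_stim: float, rate_base: float) -> float:
    """Percent rate change relative to a baseline: 100*(stim - base)/base."""
    if rate_base == 0:
        raise ZeroDivisionError("zero baseline rate; modulation undefined")
    return 100.0 * (rate_stim - rate_base) / rate_base


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) contrast values")
    return float(np.polyfit(x, y, 1)[0])


def contrast_gain_slopes(rate_mod_by_K: dict[str, dict[float, np.ndarray]],
                         n_boot: int = 1000, seed=0,
                         genotypes: tuple[str, str] = ("wt", "fhm1")) -> dict:
    """Linear contrast-gain slopes per genotype and their bootstrap ratio.

    ``rate_mod_by_K[genotype][K]`` holds per-repetition percent modulations.
    The slope is the OLS fit of the rep-mean modulation against K; the
    WT/FHM1 slope ratio is bootstrapped by resampling repetitions.

    Returns slopes, ratio mean and the 95% bootstrap confidence interval.
    """
    g0, g1 = genotypes
    Ks = sorted(rate_mod_by_K[g0])
    if len(Ks) < 3:
        raise ValueError("need at least 3 contrast levels")
    mods = {g: np.column_stack([np.asarray(rate_mod_by_K[g][K], dtype=float)
                                for K in Ks])
            for g in genotypes}  # (reps, nK)
    slopes = {g: _ols_slope(Ks, mods[g].mean(axis=0)) for g in genotypes}
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        r = {}
        for g in genotypes:
            nrep = mods[g].shape[0]
            idx = rng.integers(0, nrep, size=nrep)
            r[g] = _ols_slope(Ks, mods[g][idx].mean(axis=0))
        ratios[b] = r[g0] / r[g1]
    return {
        "slope_" + g0: slopes[g0],
        "slope_" + g1: slopes[g1],
        "ratio": slopes[g0] / slopes[g1],
        "ratio_boot_mean": float(ratios.mean()),
        "ratio_ci95": (float(np.percentile(ratios, 2.5)),
                       float(np.percentile(ratios, 97.5))),
    }


def gamma_bb_ratio(mod: SpectralModulation) -> GammaBandSplit:
    """High over low broad-gamma band-average of a modulation spectrum."""
    f = mod.freqs
    if f.min() > LOW_BB_BAND[0] or f.max() < HIGH_BB_BAND[1]:
        raise ValueError("modulation must cover 12-100 Hz")
    low = float(np.nanmean(mod.mod[(f >= LOW_BB_BAND[0]) & (f <= LOW_BB_BAND[1])]))
    high = float(np.nanmean(mod.mod[(f >= HIGH_BB_BAND[0]) & (f <= HIGH_BB_BAND[1])]))
    # sweeps can drive the low-band average through zero; return the signed
    # value flagged instead of erroring
    return GammaBandSplit(low_bb=low, high_bb=high, ratio=high / low,
                          flagged=low <= 0)


def reduced_chi_square(model, data, data_sd) -> float:
    """Mean squared z-residual between model and data spectra.

    chi2_r = mean_f [ (model(f) - data(f))^2 / sd(f)^2 ], i.e. normalized
    by the number of frequency bins with no parameter-count correction.
    """
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    sd = np.asarray(data_sd, dtype=float)
    if model.shape != data.shape or model.shape != sd.shape:
        raise ValueError("model, data and sd must share a grid")
    if np.any(sd <= 0):
        raise ValueError("data_sd must be positive")
    return float(np.mean(((model - data) / sd) ** 2))
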