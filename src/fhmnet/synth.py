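"""Synthetic laminar recordings with planted, recoverable structure.

Emulates the statistical structure of the experimental 16-channel V1
recordings so the analysis chain (VEP, CSD, MUA, scalograms, MI,
permutation statistics) is fully testable without animal data:

* 1/f background noise per channel;
* a reversal-locked VEP template (negative N1, optional later positive P2)
  with a depth profile that inverts polarity around a designated
  "layer IV" channel, giving a well-defined earliest CSD sink;
* a ~57 Hz narrow-band gamma whose amplitude decreases with contrast and
  vanishes for K >= 30;
* broad-band gamma bursts after each reversal whose band depends on the
  genotype (beta/low gamma 12-40 Hz for WT, high gamma 70-100 Hz for
  FHM1) and whose amplitude grows with contrast;
* Poisson spike transients (biphasic ~2 ms pulses) whose rate bursts
  after each reversal, with a contrast slope twice as steep for WT.

All planted effect sizes are free configuration values with defaults
chosen to mimic the qualitative experimental findings; the sidecar
returned with each recording records every planted parameter so
closed-loop tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .drives import narrowband_amplitude
from .ephys import LaminarRecording

__all__ = ["SynthConfig", "generate_recording", "generate_mi_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    n_channels: int = 16
    fs: float = 1000.0  # Hz
    spacing_um: float = 50.0
    n_reversals: int = 30
    genotype: str = "wt"
    seed: int = 0
    prestim_ms: float = 3000.0  # blank span before the stimulus
    # --- planted parameters -------------------------------------------------
    layer4_channel: int = 8
    depth_sd_ch: float = 1.5
    n1_amp_mv: float = -0.30
    n1_latency_ms: float | None = None  # default 80 (wt) / 95 (fhm1)
    n1_width_ms: float = 18.0
    p2_amp_mv: float = 0.15  # present only in wt
    p2_latency_ms: float = 150.0
    nb_center_hz: float = 57.0
    nb_gain_mv: float = 0.004  # mV per (spike/s of A(K))
    bb_gain_mv: float = 0.12  # burst amplitude at K = 90
    bb_exponent: float = 1.5  # amplitude ~ (K/90)^exponent
    mua_base_hz: float = 60.0
    mua_slope_hz_per_k: float | None = None  # default 2.0 (wt) / 1.0 (fhm1)
    mua_peak_ms: float | None = None  # default 60 (wt) / 70 (fhm1)
    mua_width_ms: float = 30.0
    spike_amp_mv: float = 0.15
    background_sd_mv: float = 0.05
    background_exponent: float = 1.0

    @property
    def is_wt(self) -> bool:
        return self.genotype == "wt"

    def resolved(self) -> dict:
        """Genotype-resolved planted parameters (the sidecar)."""
        return {
            "genotype": self.genotype,
            "layer4_channel": self.layer4_channel,
            "n1_amp_mv": self.n1_amp_mv,
            "n1_latency_ms": self.n1_latency_ms
            if self.n1_latency_ms is not None else (80.0 if self.is_wt else 95.0),
            "has_p2": self.is_wt,
            "p2_amp_mv": self.p2_amp_mv if self.is_wt else 0.0,
            "p2_latency_ms": self.p2_latency_ms,
            "nb_center_hz": self.nb_center_hz,
            "bb_band_hz": (12.0, 40.0) if self.is_wt else (70.0, 100.0),
            "mua_slope_hz_per_k": self.mua_slope_hz_per_k
            if self.mua_slope_hz_per_k is not None else (2.0 if self.is_wt else 1.0),
            "mua_peak_ms": self.mua_peak_ms
            if self.mua_peak_ms is not None else (60.0 if self.is_wt else 70.0),
        }


def _one_over_f(n: int, fs: float, exponent: float, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n)
    return (x - x.mean()) / x.std()


def _vep_template(t_ms: np.ndarray, side: dict, cfg: SynthConfig) -> np.ndarray:
    v = side["n1_amp_mv"] * np.exp(
        -0.5 * ((t_ms - side["n1_latency_ms"]) / cfg.n1_width_ms) ** 2)
    if side["has_p2"]:
        v = v + side["p2_amp_mv"] * np.exp(
            -0.5 * ((t_ms - side["p2_latency_ms"]) / 30.0) ** 2)
    return v


def _depth_profile(cfg: SynthConfig) -> np.ndarray:
    ch = np.arange(cfg.n_channels)
    c = cfg.layer4_channel
    centre = np.exp(-0.5 * ((ch - c) / cfg.depth_sd_ch) ** 2)
    surround = np.exp(-0.5 * ((ch - c) / (3.0 * cfg.depth_sd_ch)) ** 2)
    prof = 1.5 * centre - 0.5 * surround  # polarity inversion off-centre
    return prof / prof[c]


def _bandpassed_noise(n: int, fs: float, band, rng) -> np.ndarray:
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + 500))[500:]
    return x / x.std()


def generate_recording(cfg: SynthConfig, K) -> tuple[LaminarRecording, dict]:
    """Synthesize one contrast-level recording plus its ground-truth sidecar."""
    side = cfg.resolved()
    side["K"] = K
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed, 0 if K == "pre" else int(K) + 1]))
    fs = cfg.fs
    stim_ms = cfg.n_reversals * 1000.0
    n = int(round((cfg.prestim_ms + stim_ms) * 1e-3 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    reversal_times = cfg.prestim_ms + 1000.0 * np.arange(cfg.n_reversals)
    stim_mask = t_ms >= cfg.prestim_ms
    profile = _depth_profile(cfg)

    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        data[c] = cfg.background_sd_mv * _one_over_f(
            n, fs, cfg.background_exponent, rng)

    # reversal-locked VEP, depth-scaled
    ep_t = np.arange(0, 500)  # ms at 1 kHz
    template = _vep_template(ep_t.astype(float), side, cfg)
    vep_add = np.zeros(n)
    for rt in reversal_times:
        i = int(round(rt * 1e-3 * fs))
        vep_add[i:i + ep_t.size] += template[:max(0, min(ep_t.size, n - i))]
    data += profile[:, None] * vep_add[None, :]

    # narrow-band gamma, contrast-dependent amplitude, stimulus span only
    A = narrowband_amplitude(K)
    if A > 0:
        nb = _bandpassed_noise(n, fs, (cfg.nb_center_hz - 5, cfg.nb_center_hz + 5),
                               rng)
        data += (cfg.nb_gain_mv * A) * (profile[:, None] * (nb * stim_mask)[None, :])

    # broad-band gamma bursts after each reversal, genotype-specific band
    Knum = 0.0 if K == "pre" else float(K)
    bb_amp = cfg.bb_gain_mv * (Knum / 90.0) ** cfg.bb_exponent
    if bb_amp > 0:
        carrier = _bandpassed_noise(n, fs, side["bb_band_hz"], rng)
        envelope = np.zeros(n)
        burst_t = np.arange(0, 150)
        burst = np.exp(-0.5 * ((burst_t - 50.0) / 35.0) ** 2)
        for rt in reversal_times:
            i = int(round(rt * 1e-3 * fs))
            envelope[i:i + burst_t.size] += burst[:max(0, min(burst_t.size, n - i))]
        data += bb_amp * (profile[:, None] * (carrier * envelope)[None, :])

    # Poisson spike transients for MUA, rate bursting after reversals
    rate = np.full(n, cfg.mua_base_hz)
    burst_amp = side["mua_slope_hz_per_k"] * Knum
    for rt in reversal_times:
        rate += burst_amp * np.exp(
            -0.5 * ((t_ms - rt - side["mua_peak_ms"]) / cfg.mua_width_ms) ** 2)
    counts = rng.poisson(rate / fs)
    spike_shape = cfg.spike_amp_mv * np.array([0.4, 1.0, -0.7, 0.1])
    spike_train = np.convolve(counts.astype(float), spike_shape, mode="same")
    data += profile[:, None] * spike_train[None, :]

    rec = LaminarRecording(data=data, fs=fs, spacing_um=cfg.spacing_um,
                           reversal_times=reversal_times, K=K,
                           prestim_span=(0.0, cfg.prestim_ms))
    side["mua_burst_hz"] = burst_amp
    side["bb_amp_mv"] = bb_amp
    return rec, side


def generate_mi_dataset(n_trials_per_K: int, effect: str = "planted",
                        seed=0, contrasts=(0, 6, 8, 10, 15, 20, 30, 50, 90),
                        snr: float = 1.0):
    """Stimulus/response pairs for calibrating the MI estimator.

    ``effect='none'`` draws responses independent of the contrast;
    ``'planted'`` makes the response mean increase monotonically with the
    contrast rank, with unit noise and signal amplitude ``snr``.

    Returns (stimuli, responses) arrays of length n_trials_per_K * len(contrasts).
    """
    if effect not in ("none", "planted"):
        raise ValueError("effect must be 'none' or 'planted'")
    rng = np.random.default_rng(seed)
    stimuli = np.repeat(np.arange(len(contrasts)), n_trials_per_K)
    responses = rng.standard_normal(stimuli.size)
    if effect == "planted":
        responses = responses + snr * stimuli
    return stimuli, responses
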