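"""External (non-recurrent) drives: sustained thalamic, narrow-band gamma, cortical noise.

All three drives are realized as independent inhomogeneous Poisson spike
trains, one train per (neuron, drive), sharing a common rate trace:

* sustained thalamic: constant rate S(K) [spikes/s], non-decreasing in
  contrast K;
* narrow-band thalamic: rate [A(K) * eps_gamma(t)]_+, where eps_gamma is
  z-scored white noise band-passed around 57 Hz (10 Hz bandwidth,
  3rd-order Butterworth), and the amplitude A(K) [spikes/s] decreases
  with contrast (zero for K >= 30);
* cortical noise: rate [theta_n * n(t)]_+ with n(t) z-scored 1/f^1.5
  colored noise and theta_n = 0.4 spikes/ms.

[x]_+ denotes threshold-linear rectification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "RateTrace",
    "ThalamicDrive",
    "CorticalNoise",
    "CONTRASTS",
    "PRE_STIMULUS",
    "sustained_rate",
    "narrowband_amplitude",
    "narrowband_envelope",
    "colored_noise",
    "colored_noise_rate",
    "poisson_counts",
    "poisson_trains",
]

#: the nine supported contrast levels
CONTRASTS = (0, 6, 8, 10, 15, 20, 30, 50, 90)
#: sentinel for the blank pre-stimulus condition
PRE_STIMULUS = "pre"

_S_OF_K = {0: 1000.0, 6: 1000.0, 8: 1000.0, 10: 1000.0, 15: 1000.0,
           20: 1000.0, 30: 1000.0, 50: 1040.0, 90: 1080.0,
           PRE_STIMULUS: 1000.0}
_A_OF_K = {0: 50.0, 6: 45.0, 8: 40.0, 10: 30.0, 15: 22.5, 20: 15.0,
           30: 0.0, 50: 0.0, 90: 0.0, PRE_STIMULUS: 0.0}
# Note: A(15) is not printed in the source table (A is given at
# K = 0, 6, 8, 10, 20); the midpoint of the neighbouring values is used.


@dataclass
class RateTrace:
    """Instantaneous Poisson rate [spikes/s] on the simulation grid."""

    dt: float  # ms
    rate: np.ndarray  # spikes/s, rectified

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.rate.size) * self.dt

    @property
    def duration(self) -> float:
        return self.rate.size * self.dt

    def expected_count(self) -> float:
        """Expected number of spikes per train, integral of rate dt."""
        return float(np.sum(self.rate) * self.dt * 1e-3)


def _lookup(table: dict, K) -> float:
    if isinstance(K, str):
        if K != PRE_STIMULUS:
            raise ValueError(f"unknown condition {K!r}")
        return table[PRE_STIMULUS]
    if K not in table:
        raise ValueError(f"unsupported contrast level K={K!r}; "
                         f"supported: {CONTRASTS} or 'pre'")
    return table[K]


def sustained_rate(K) -> float:
    """Sustained thalamic rate S(K) [spikes/s]; K may be 'pre'."""
    return _lookup(_S_OF_K, K)


def narrowband_amplitude(K) -> float:
    """Narrow-band amplitude A(K) [spikes/s]; zero for K >= 30 and 'pre'."""
    return _lookup(_A_OF_K, K)


def narrowband_envelope(duration: float, dt: float, seed,
                        center: float = 57.0, bandwidth: float = 10.0,
                        order: int = 3) -> RateTrace:
    """Unit-variance gamma-band envelope eps_gamma(t).

    White noise band-passed with a 3rd-order Butterworth filter centred at
    57 Hz with 10 Hz bandwidth, then z-scored so A(K) sets the modulation
    scale in spikes/s.  Not rectified (rectification happens after scaling
    by A(K)).
    """
    fs = 1000.0 / dt  # Hz
    if center + bandwidth / 2 >= fs / 2:
        raise ValueError("dt too coarse for the requested band (Nyquist)")
    n = int(round(duration / dt))
    if duration < 200.0:
        raise ValueError("duration too short for the band-pass transient")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n + int(500 / dt))  # pad to absorb transient
    sos = signal.butter(order, [center - bandwidth / 2, center + bandwidth / 2],
                        btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, white)[-n:]
    x = (x - x.mean()) / x.std()
    return RateTrace(dt=dt, rate=x)


def colored_noise(n: int, dt: float, exponent: float, rng) -> np.ndarray:
    """Z-scored colored noise with PSD proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=dt * 1e-3)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n)
    return (x - x.mean()) / x.std()


def colored_noise_rate(duration: float, dt: float, theta_n: float = 0.4,
                       seed=None, exponent: float = 1.5) -> RateTrace:
    """Cortical-noise rate [theta_n * n(t)]_+ converted to spikes/s.

    theta_n is in spikes/ms (0.4 by default), so the returned rate is
    1000 * theta_n * n(t), rectified.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    trace = colored_noise(n, dt, exponent, rng)
    rate = np.clip(1000.0 * theta_n * trace, 0.0, None)
    return RateTrace(dt=dt, rate=rate)


@dataclass(frozen=True)
class ThalamicDrive:
    """Contrast-to-rate maps and narrow-band filter parameters."""

    nb_center: float = 57.0
    nb_bandwidth: float = 10.0
    nb_filter_order: int = 3

    def sustained(self, K) -> float:
        return sustained_rate(K)

    def narrowband_rate(self, K, duration: float, dt: float, seed) -> RateTrace:
        A = narrowband_amplitude(K)
        if A == 0.0:
            n = int(round(duration / dt))
            return RateTrace(dt=dt, rate=np.zeros(n))
        env = narrowband_envelope(duration, dt, seed, self.nb_center,
                                  self.nb_bandwidth, self.nb_filter_order)
        return RateTrace(dt=dt, rate=np.clip(A * env.rate, 0.0, None))


@dataclass(frozen=True)
class CorticalNoise:
    """Stimulus-unspecific colored-noise drive parameters.

    With ``per_neuron`` (the default) every neuron has its own independent
    z-scored 1/f^1.5 rate trace; this slow per-neuron rate fluctuation
    (std theta_n = 0.4 spikes/ms) is what keeps the network in a tonic,
    fluctuation-driven balanced state.  Set it to False to share a single
    noise trace across neurons (independent Poisson spikes either way).
    """

    theta_n: float = 0.4  # spikes/ms
    spectral_exponent: float = 1.5
    per_neuron: bool = True

    def rate(self, duration: float, dt: float, seed) -> RateTrace:
        return colored_noise_rate(duration, dt, self.theta_n, seed,
                                  self.spectral_exponent)

    def coarse_rates(self, duration: float, coarse_dt: float,
                     n_neurons: int, seed) -> np.ndarray:
        """Rectified per-neuron rate traces [spikes/s] on a coarse grid.

        Shape (n_neurons, n_coarse); a single shared trace broadcast to all
        rows when ``per_neuron`` is False.
        """
        n_coarse = int(round(duration / coarse_dt))
        rng = np.random.default_rng(seed)
        rows = n_neurons if self.per_neuron else 1
        white = rng.standard_normal((rows, n_coarse))
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n_coarse, d=coarse_dt * 1e-3)
        amp = np.ones_like(f)
        amp[1:] = f[1:] ** (-self.spectral_exponent / 2.0)
        amp[0] = 0.0
        x = np.fft.irfft(spec * amp[None, :], n=n_coarse, axis=1)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        rate = np.clip(1000.0 * self.theta_n * x, 0.0, None)
        if not self.per_neuron:
            rate = np.broadcast_to(rate, (n_neurons, n_coarse)).copy()
        return rate


def poisson_counts(rate: RateTrace, n_neurons: int, seed) -> np.ndarray:
    """Per-neuron, per-step Poisson event counts, shape (n_neurons, n_steps).

    Each neuron receives an independent realization of an inhomogeneous
    Poisson process with the shared rate trace; counts per step are
    Poisson(rate * dt).  Generated in time chunks to bound memory.
    """
    if np.any(rate.rate < 0):
        raise ValueError("rate must be rectified (non-negative)")
    rng = np.random.default_rng(seed)
    lam = rate.rate * rate.dt * 1e-3
    n_steps = lam.size
    out = np.empty((n_neurons, n_steps), dtype=np.uint8)
    chunk = max(1, int(4e6 // max(n_neurons, 1)))
    for i in range(0, n_steps, chunk):
        out[:, i:i + chunk] = rng.poisson(
            lam[None, i:i + chunk], size=(n_neurons, min(chunk, n_steps - i))
        ).astype(np.uint8)
    return out


def scattered_poisson_counts(rate_coarse: np.ndarray, coarse_dt: float,
                             n_neurons: int, fine_dt: float, seed,
                             out: np.ndarray | None = None) -> np.ndarray:
    """Poisson event counts on a fine grid from a coarse piecewise-constant rate.

    Counts are drawn per coarse bin (Poisson with mean rate*coarse_dt) and
    each event is placed uniformly at random in one of the fine sub-steps,
    which samples the same inhomogeneous Poisson process as per-fine-step
    draws whenever the rate is constant within a coarse bin.  Much cheaper
    than fine-grid sampling for band-limited rates.

    Returns (or fills) an array of shape (n_fine_steps, n_neurons), uint8.
    """
    if np.any(rate_coarse < 0):
        raise ValueError("rate must be rectified (non-negative)")
    sub = int(round(coarse_dt / fine_dt))
    n_coarse = rate_coarse.shape[-1]
    n_fine = n_coarse * sub
    rng = np.random.default_rng(seed)
    lam = rate_coarse * coarse_dt * 1e-3
    if rate_coarse.ndim == 1:
        counts = rng.poisson(lam[None, :], size=(n_neurons, n_coarse))
    else:
        counts = rng.poisson(lam)
    if out is None:
        out = np.zeros((n_fine, n_neurons), dtype=np.uint8)
    else:
        out[:] = 0
    nz_neuron, nz_bin = np.nonzero(counts)
    reps = counts[nz_neuron, nz_bin]
    ev_neuron = np.repeat(nz_neuron, reps)
    ev_bin = np.repeat(nz_bin, reps)
    ev_step = ev_bin * sub + rng.integers(0, sub, size=ev_bin.size)
    np.add.at(out.reshape(-1), ev_step * n_neurons + ev_neuron, 1)
    return out


def poisson_trains(rate: RateTrace, n_neurons: int, seed) -> list[np.ndarray]:
    """Per-neuron spike-time lists [ms] from independent Poisson realizations."""
    counts = poisson_counts(rate, n_neurons, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(1e9), _as_int(seed)]))
    trains = []
    for row in counts:
        steps = np.repeat(np.nonzero(row)[0], row[np.nonzero(row)[0]])
        times = (steps + rng.random(steps.size)) * rate.dt
        trains.append(np.sort(times))
    return trains


def _as_int(seed) -> int:
    if seed is None:
        return 0
    return int(np.random.SeedSequence(seed).entropy) % (2**31)
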