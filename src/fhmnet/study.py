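"""Desk-scale contrast study: WT vs FHM1 across the nine contrast levels.

This module reproduces the simulation findings of the migraine model at a
reduced problem size chosen for a single CPU:

* the network is 1000 excitatory + 250 inhibitory neurons with connection
  probability 0.8, which preserves the full-size model's per-neuron
  in-degrees (800 excitatory, 200 inhibitory inputs) and every printed
  conductance exactly — only the pool size and the input correlations
  shrink;
* each condition is simulated for 1200 ms (the first 200 ms discarded),
  10 repetitions per condition with independent drive realizations and a
  connectivity graph shared by both genotypes.

Quantities computed:

* t-like contrast gain: percent modulation of the population ("MUA") rate
  vs the pre-stimulus baseline per contrast K, the OLS slope vs K per
  genotype, and the WT/FHM1 slope ratio with a bootstrap CI;
* synaptic-alteration sweep modulations: percent change of the baseline
  population rates when one alteration (TC or IC) is moved from 0 to its
  FHM1-fit reference while the other two stay at reference;
* I/E current ratios per contrast and genotype;
* pre-stimulus and K = 90 LFP-proxy spectra for the spectral-shift
  analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .drives import CONTRASTS, PRE_STIMULUS
from .engine import SimulationConfig, run_simulation
from .measures import contrast_gain_slopes, ie_ratio, psd_welch, zscore
from .network import (FHM1_REFERENCE, FHM1Params, NetworkSpec,
                      apply_fhm1, build_connectivity, wt_conductances)

__all__ = ["StudyConfig", "StudyResult", "run_contrast_study",
           "sweep_rate_modulations", "acceptance_targets"]


@dataclass(frozen=True)
class StudyConfig:
    n_e: int = 1000
    n_i: int = 250
    p_conn: float = 0.2
    #: recurrent (AMPA + GABA) conductances are multiplied by this factor
    #: to preserve the full-size model's mean recurrent drive at the
    #: reduced pool size (N_full / N = 4); the printed connection
    #: probability and the shared-input correlation structure stay intact
    recurrent_scale: float = 4.0
    duration: float = 1200.0  # ms
    discard: float = 200.0  # ms
    dt: float = 0.05  # ms
    n_reps: int = 10
    contrasts: tuple = CONTRASTS
    fhm1: FHM1Params = FHM1_REFERENCE
    keep_lfp_for: tuple = (PRE_STIMULUS, 90)

    def sim_config(self, seed: int, record: bool = True) -> SimulationConfig:
        return SimulationConfig(dt=self.dt, duration=self.duration,
                                discard=self.discard, seed=seed,
                                record_currents=record)


@dataclass
class StudyResult:
    config: StudyConfig
    #: rates[genotype][K] -> (n_reps, 2) array of (exc, inh) rates [sp/s]
    rates: dict
    #: ie[genotype][K] -> (n_reps, 2) array of (ie_total, ie_recurrent)
    ie: dict
    #: lfp[genotype][K] -> list of LFP proxy traces (kept conditions only)
    lfp: dict

    def mua_rate(self, genotype: str, K) -> np.ndarray:
        """Per-rep population rate (exc and inh pooled) [spikes/s]."""
        r = self.rates[genotype][K]
        ne, ni = self.config.n_e, self.config.n_i
        return (r[:, 0] * ne + r[:, 1] * ni) / (ne + ni)

    def mua_modulation(self, genotype: str) -> dict:
        """Per-contrast per-rep percent modulation vs the pre-stimulus rate.

        Repetition i of each stimulation condition is paired with baseline
        repetition i.
        """
        base = self.mua_rate(genotype, PRE_STIMULUS)
        return {K: 100.0 * (self.mua_rate(genotype, K) - base) / base
                for K in self.config.contrasts}

    def slope_ratio(self, n_boot: int = 1000, seed: int = 0) -> dict:
        mods = {g: self.mua_modulation(g) for g in ("wt", "fhm1")}
        return contrast_gain_slopes(mods, n_boot=n_boot, seed=seed)

    def mean_psd(self, genotype: str, K, fs: float | None = None):
        """Rep-averaged Welch PSD of the z-scored LFP proxy."""
        fs = fs or 1000.0 / self.config.dt
        psds = [psd_welch(zscore(tr), fs=fs)[1] for tr in self.lfp[genotype][K]]
        f = psd_welch(zscore(self.lfp[genotype][K][0]), fs=fs)[0]
        return f, np.mean(psds, axis=0)


def _study_conductances(cfg: StudyConfig, params=None):
    g = apply_fhm1(wt_conductances(), params) if params else wt_conductances()
    return g.scaled_recurrent(cfg.recurrent_scale)


def _genotype_networks(cfg: StudyConfig, seed: int):
    conn = build_connectivity(cfg.n_e, cfg.n_i, cfg.p_conn, seed=seed)
    wt = NetworkSpec(connectivity=conn, conductances=_study_conductances(cfg))
    fhm1 = NetworkSpec(connectivity=conn,
                       conductances=_study_conductances(cfg, cfg.fhm1))
    return {"wt": wt, "fhm1": fhm1}


def _run_block(net: NetworkSpec, K, cfg: StudyConfig, seeds, keep_lfp: bool):
    rates = np.empty((cfg.n_reps, 2))
    ies = np.empty((cfg.n_reps, 2))
    lfps = []
    for i, s in enumerate(seeds):
        res = run_simulation(net, K, cfg.sim_config(seed=int(s)))
        rates[i] = (res.rates["exc"], res.rates["inh"])
        r = ie_ratio(res.currents, K=K)
        ies[i] = (r.ie_total, r.ie_recurrent)
        if keep_lfp:
            lfps.append(res.lfp)
    return rates, ies, lfps


def _spawn_seeds(root: np.random.SeedSequence, n: int):
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n)]


def run_contrast_study(seed: int, cfg: StudyConfig = StudyConfig(),
                       progress=None) -> StudyResult:
    """Simulate both genotypes at baseline and all contrasts."""
    root = np.random.SeedSequence(seed)
    conn_seed = int(root.generate_state(1)[0] % (2 ** 31))
    nets = _genotype_networks(cfg, conn_seed)
    conditions = [PRE_STIMULUS, *cfg.contrasts]
    # common random numbers: repetition i uses the same drive seed in every
    # condition and genotype, so each slow cortical-noise realization and
    # initial state is shared and modulations are within-pair differences
    rep_seeds = _spawn_seeds(root.spawn(1)[0], cfg.n_reps)
    rates: dict = {}
    ie: dict = {}
    lfp: dict = {}
    for g in ("wt", "fhm1"):
        rates[g], ie[g], lfp[g] = {}, {}, {}
        for K in conditions:
            keep = K in cfg.keep_lfp_for
            r, i, l = _run_block(nets[g], K, cfg, rep_seeds, keep)
            rates[g][K], ie[g][K] = r, i
            if keep:
                lfp[g][K] = l
            if progress:
                progress(g, K)
    return StudyResult(config=cfg, rates=rates, ie=ie, lfp=lfp)


def sweep_rate_modulations(seed: int, cfg: StudyConfig = StudyConfig(),
                           reference_baseline: np.ndarray | None = None,
                           progress=None) -> dict:
    """Percent change of baseline population rates along the TC, IC and TCA sweeps.

    For each swept alteration the other two stay at their FHM1-fit
    reference; the modulation is the rate at the reference value of the
    swept alteration relative to the rate at zero:

        100 * (rate(x = ref) - rate(x = 0)) / rate(x = 0)

    computed on the blank (pre-stimulus) condition.  ``reference_baseline``
    may pass in the (n_reps, 2) baseline rates of the full FHM1-fit network
    (e.g. from a contrast study) to avoid re-simulating it.

    Returns {"tc": {"inh": %, "exc": %}, "ic": {...}, "tca": {...}}.
    """
    ref = cfg.fhm1
    origins = {
        "tc": replace(ref, tc_incr_pct=0.0),
        "ic": replace(ref, cc_incr_pct=0.0),
        "tca": replace(ref, tca_pct=0.0),
    }
    root = np.random.SeedSequence(seed)
    conn_seed = int(root.generate_state(1)[0] % (2 ** 31))
    conn = build_connectivity(cfg.n_e, cfg.n_i, cfg.p_conn, seed=conn_seed)
    # common random numbers across the sweep conditions (see run_contrast_study)
    rep_seeds = _spawn_seeds(root.spawn(1)[0], cfg.n_reps)
    if reference_baseline is None:
        net_ref = NetworkSpec(connectivity=conn,
                              conductances=_study_conductances(cfg, ref))
        reference_baseline, _, _ = _run_block(
            net_ref, PRE_STIMULUS, cfg, rep_seeds, False)
        if progress:
            progress("reference", PRE_STIMULUS)
    out = {}
    ref_mean = reference_baseline.mean(axis=0)  # (exc, inh)
    for name, params in origins.items():
        net0 = NetworkSpec(connectivity=conn,
                           conductances=_study_conductances(cfg, params))
        r0, _, _ = _run_block(net0, PRE_STIMULUS, cfg, rep_seeds, False)
        m0 = r0.mean(axis=0)
        out[name] = {
            "inh": float(100.0 * (ref_mean[1] - m0[1]) / m0[1]),
            "exc": float(100.0 * (ref_mean[0] - m0[0]) / m0[0]),
        }
        if progress:
            progress(name, PRE_STIMULUS)
    return out


def acceptance_targets(seed: int, cfg: StudyConfig = StudyConfig(),
                       study: StudyResult | None = None,
                       progress=None) -> dict:
    """Recompute the headline simulation quantities from scratch.

    Returns a dict with the WT/FHM1 contrast-gain slope ratio and the four
    sweep modulations (TC and IC, inhibitory and excitatory), on the percent
    scale used in the source figures.
    """
    root = np.random.SeedSequence([seed, 0xFACE])
    s_study, s_sweep, s_boot = [int(s.generate_state(1)[0] % (2 ** 31))
                                for s in root.spawn(3)]
    if study is None:
        study = run_contrast_study(s_study, cfg, progress=progress)
    slopes = study.slope_ratio(n_boot=1000, seed=s_boot)
    # the sweep re-simulates its own reference baseline so that all three
    # sweep conditions share one connectivity graph
    sweeps = sweep_rate_modulations(s_sweep, cfg, progress=progress)
    n_sim = (study.config.n_e + study.config.n_i)
    return {
        "slope_ratio": slopes["ratio_boot_mean"],
        "tc_inh_pct": sweeps["tc"]["inh"],
        "tc_exc_pct": sweeps["tc"]["exc"],
        "ic_inh_pct": sweeps["ic"]["inh"],
        "ic_exc_pct": sweeps["ic"]["exc"],
        "tca_inh_pct": sweeps["tca"]["inh"],
        "tca_exc_pct": sweeps["tca"]["exc"],
        "n_neurons": n_sim,
        "n_reps": study.config.n_reps,
        "study": study,
        "slopes": slopes,
    }
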