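"""Network definition: neuron populations, synapse kinetics, conductances, FHM1 transform.

The model is a sparse random network of leaky integrate-and-fire neurons
(80% excitatory with AMPA-like synapses, 20% inhibitory with GABA-like
synapses) receiving three non-recurrent drives (sustained thalamic,
narrow-band gamma thalamic, and colored cortical noise).  Familial
hemiplegic migraine type 1 (FHM1) is modelled purely as a gain-of-function
of glutamatergic conductances: an intra-cortical (IC) increase of the
recurrent AMPA conductances, a thalamocortical (TC) increase of the
sustained thalamic conductances, and a thalamocortical asymmetry (TCA)
that makes the TC increase larger onto inhibitory than excitatory
neurons.  GABAergic conductances are never altered.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields, replace

import numpy as np
import scipy.sparse as sp
import yaml

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "ConductanceSet",
    "FHM1Params",
    "Connectivity",
    "NetworkSpec",
    "build_connectivity",
    "wt_conductances",
    "apply_fhm1",
    "synaptic_current",
    "synaptic_trace_increment",
    "trace_peak_time",
    "EXC_NEURON",
    "INH_NEURON",
    "GABA_KINETICS",
    "AMPA_ON_EXC",
    "AMPA_ON_INH",
]

V_AMPA = 0.0  # mV, AMPA reversal
V_GABA = -80.0  # mV, GABA reversal


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire single-neuron parameters.

    ``tau_m`` [ms] and ``g_leak`` [nS] differ between populations
    (20 ms / 25 nS excitatory, 10 ms / 20 nS inhibitory).  Threshold,
    reset and refractory period are inherited from the model lineage
    (threshold 18 mV above rest) and are exposed so they can be
    re-calibrated from config.
    """

    tau_m: float
    g_leak: float
    V_leak: float = -70.0
    V_thresh: float = -52.0
    V_reset: float = -59.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.g_leak <= 0:
            raise ValueError("tau_m and g_leak must be positive")
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must lie below V_thresh")


EXC_NEURON = NeuronParams(tau_m=20.0, g_leak=25.0, tau_ref=2.0)
INH_NEURON = NeuronParams(tau_m=10.0, g_leak=20.0, tau_ref=1.0)


@dataclass(frozen=True)
class SynapseKinetics:
    """Difference-of-exponentials synapse kinetics.

    tau_l: axonal latency [ms]; tau_r/tau_d: rise/decay times [ms];
    V_syn: reversal potential [mV].
    """

    tau_l: float
    tau_r: float
    tau_d: float
    V_syn: float

    def __post_init__(self) -> None:
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("require tau_d > tau_r > 0")


GABA_KINETICS = SynapseKinetics(tau_l=1.0, tau_r=1.0, tau_d=5.0, V_syn=V_GABA)
# Glutamatergic kinetics follow the model lineage: the faster AMPA synapse
# (0.2 / 1.25 ms) is the one onto interneurons, the slower one
# (0.4 / 2.25 ms) onto pyramidal cells.  With the opposite assignment the
# recurrent excitatory loop reverberates faster than feedback inhibition
# can engage and the network has no stable low-rate state.
AMPA_ON_EXC = SynapseKinetics(tau_l=2.0, tau_r=0.4, tau_d=2.25, V_syn=V_AMPA)
AMPA_ON_INH = SynapseKinetics(tau_l=2.0, tau_r=0.2, tau_d=1.25, V_syn=V_AMPA)


@dataclass(frozen=True)
class ConductanceSet:
    """One conductance [nS] per pathway x target population."""

    g_gaba_inh: float = 2.70
    g_gaba_exc: float = 2.01
    g_ampa_inh: float = 0.233
    g_ampa_exc: float = 0.178
    g_thal_s_inh: float = 0.317
    g_thal_s_exc: float = 0.234
    g_thal_nb_inh: float = 0.317
    g_thal_nb_exc: float = 0.234
    g_noise_inh: float = 0.317
    g_noise_exc: float = 0.234

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative conductance {f.name}")

    def scaled_recurrent(self, factor: float) -> "ConductanceSet":
        """Scale only recurrent (AMPA + GABA) conductances, e.g. for density-scaled nets."""
        return replace(
            self,
            g_gaba_inh=self.g_gaba_inh * factor,
            g_gaba_exc=self.g_gaba_exc * factor,
            g_ampa_inh=self.g_ampa_inh * factor,
            g_ampa_exc=self.g_ampa_exc * factor,
        )

    def to_csv(self) -> str:
        """Conductance table as CSV text for audit."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["pathway_target", "g_nS"])
        for f in fields(self):
            w.writerow([f.name, getattr(self, f.name)])
        return buf.getvalue()


def wt_conductances() -> ConductanceSet:
    """The wild-type conductance table."""
    return ConductanceSet()


@dataclass(frozen=True)
class FHM1Params:
    """The three FHM1 synaptic alteration percentages.

    cc_incr_pct: intra-cortical AMPA increase (IC), %.
    tc_incr_pct: thalamocortical increase (TC), %.
    tca_pct:     thalamocortical asymmetry (TCA), %; alpha = 1 + TCA%/100.

    The reference FHM1 fit is (IC, TC, TCA) = (40, 30, 40).
    """

    cc_incr_pct: float = 0.0
    tc_incr_pct: float = 0.0
    tca_pct: float = 0.0
    #: apply the TC gain-of-function to the narrow-band thalamic synapses too.
    #: Off by default: the short-term depression of FHM1 thalamocortical
    #: synapses onto excitatory neurons wanes the gain at the sustained
    #: ~60 Hz firing of the LGN neurons generating the narrow band.
    scale_narrowband: bool = False

    @property
    def alpha(self) -> float:
        return 1.0 + self.tca_pct / 100.0

    @property
    def thal_inh_factor(self) -> float:
        a = self.alpha
        return 1.0 + a * 2.0 * (self.tc_incr_pct / 100.0) / (1.0 + a)

    @property
    def thal_exc_factor(self) -> float:
        a = self.alpha
        return 1.0 + 2.0 * (self.tc_incr_pct / 100.0) / (1.0 + a)

    @property
    def ic_factor(self) -> float:
        return 1.0 + self.cc_incr_pct / 100.0


#: reference fit reproducing the FHM1 experimental data
FHM1_REFERENCE = FHM1Params(cc_incr_pct=40.0, tc_incr_pct=30.0, tca_pct=40.0)


def apply_fhm1(base: ConductanceSet, f: FHM1Params) -> ConductanceSet:
    """Apply the FHM1 conductance transform to a wild-type conductance set.

    Recurrent AMPA conductances (both targets) are scaled by 1 + IC%/100.
    Sustained thalamic conductances are scaled by 1 + alpha*2*(TC/100)/(1+alpha)
    onto inhibitory and 1 + 2*(TC/100)/(1+alpha) onto excitatory targets, so
    the mean fractional increase is TC/100 and the inh/exc increase ratio is
    alpha.  GABA and cortical-noise conductances are untouched.
    """
    kwargs = dict(
        g_ampa_inh=base.g_ampa_inh * f.ic_factor,
        g_ampa_exc=base.g_ampa_exc * f.ic_factor,
        g_thal_s_inh=base.g_thal_s_inh * f.thal_inh_factor,
        g_thal_s_exc=base.g_thal_s_exc * f.thal_exc_factor,
    )
    if f.scale_narrowband:
        kwargs["g_thal_nb_inh"] = base.g_thal_nb_inh * f.thal_inh_factor
        kwargs["g_thal_nb_exc"] = base.g_thal_nb_exc * f.thal_exc_factor
    out = replace(base, **kwargs)
    return out


@dataclass(frozen=True)
class Connectivity:
    """Sparse directed adjacency, excitatory neurons first.

    C[j, k] nonzero means neuron j projects to neuron k.  No
    self-connections.
    """

    n_e: int
    n_i: int
    p_conn: float
    adjacency: sp.csr_matrix = field(repr=False)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    @property
    def density(self) -> float:
        n = self.n
        return self.adjacency.nnz / (n * (n - 1))


def build_connectivity(n_e: int, n_i: int, p: float, seed: int) -> Connectivity:
    """Sparse random directed graph; every ordered non-self pair with prob. p."""
    if n_e <= 0 or n_i < 0:
        raise ValueError("population counts must be positive")
    if not (0.0 <= p <= 1.0):
        raise ValueError("connection probability must be in [0, 1]")
    n = n_e + n_i
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    adj = sp.csr_matrix(mask, dtype=np.int8)
    return Connectivity(n_e=n_e, n_i=n_i, p_conn=p, adjacency=adj, seed=seed)


def synaptic_current(g: float, s, V, V_syn: float):
    """Synaptic current I = g * s * (V_syn - V)  [nS * mV].

    With this orientation, inserted into tau_m dV/dt = -V + V_leak +
    I_tot/g_leak, AMPA (V_syn = 0) depolarizes and GABA (V_syn = -80 mV)
    hyperpolarizes any neuron above -80 mV.
    """
    return g * np.asarray(s) * (V_syn - np.asarray(V))


def synaptic_trace_increment(t, t_spike: float, kin: SynapseKinetics, tau_m: float):
    """Closed-form synaptic trace after a single presynaptic spike at t_spike.

    ds(t) = tau_m/(tau_d - tau_r) * [exp(-(t - tau_l - t*)/tau_d)
                                     - exp(-(t - tau_l - t*)/tau_r)]
    for t >= t_spike + tau_l, zero before.  tau_m is the postsynaptic
    membrane time constant (the trace scales the postsynaptic current).
    """
    if kin.tau_d == kin.tau_r:
        raise ValueError("degenerate kinetics: tau_d == tau_r")
    t = np.asarray(t, dtype=float)
    u = t - kin.tau_l - t_spike
    out = np.where(
        u >= 0,
        tau_m / (kin.tau_d - kin.tau_r)
        * (np.exp(-np.clip(u, 0, None) / kin.tau_d)
           - np.exp(-np.clip(u, 0, None) / kin.tau_r)),
        0.0,
    )
    return out


def trace_peak_time(kin: SynapseKinetics) -> float:
    """Time after latency at which the difference of exponentials peaks."""
    return (kin.tau_d * kin.tau_r / (kin.tau_d - kin.tau_r)
            * np.log(kin.tau_d / kin.tau_r))


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable description of the full network."""

    connectivity: Connectivity
    conductances: ConductanceSet = field(default_factory=wt_conductances)
    exc: NeuronParams = EXC_NEURON
    inh: NeuronParams = INH_NEURON

    def to_yaml(self) -> str:
        """Human-readable key-value dump of everything but the adjacency."""
        d = {
            "populations": {
                "n_e": self.connectivity.n_e,
                "n_i": self.connectivity.n_i,
                "p_conn": self.connectivity.p_conn,
                "seed": self.connectivity.seed,
            },
            "exc": {f.name: getattr(self.exc, f.name) for f in fields(self.exc)},
            "inh": {f.name: getattr(self.inh, f.name) for f in fields(self.inh)},
            "conductances_nS": {
                f.name: getattr(self.conductances, f.name)
                for f in fields(self.conductances)
            },
        }
        return yaml.safe_dump(d, sort_keys=False)
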