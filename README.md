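# fhmnet

A spiking-network model of mouse primary visual cortex (V1) carrying the
synaptic alterations of familial hemiplegic migraine type 1 (FHM1),
together with the electrophysiology analysis stack needed to study how
those alterations reshape contrast encoding: LFP spectra and wavelet
scalograms, laminar VEP/CSD/MUA analysis, mutual information with
limited-sampling bias correction, and non-parametric permutation
statistics.

## The science

FHM1 is a monogenic migraine caused by Ca_V2.1 gain-of-function. In the
knock-in mouse it strengthens glutamatergic transmission at
thalamocortical (TC) and intra-cortical (IC) synapses, and — because
short-term depression is enhanced only at thalamocortical synapses onto
excitatory cells — the TC gain is effectively larger onto inhibitory
neurons (thalamocortical asymmetry, TCA). GABAergic transmission is
unaltered. The question the model addresses: how do these three
microscopic changes reshape network-level visual responses — firing-rate
contrast gain, the inhibition/excitation (I/E) balance, and the gamma
bands that encode contrast?

The network is 4000 excitatory + 1000 inhibitory leaky integrate-and-fire
neurons (connection probability 0.2) with conductance-based AMPA/GABA
synapses,

    tau_m dV/dt = -(V - V_leak) + I_tot/g_leak,
    I_syn = g_syn s_syn(t) (V_syn - V),

driven by sustained thalamic input S(K) that grows with contrast K, a
~57 Hz narrow-band thalamic gamma drive A(K)·eps(t) that shrinks with
contrast, and per-neuron 1/f^1.5 cortical noise. FHM1 scales the AMPA
conductances: recurrent by 1 + IC/100, sustained-thalamic by
1 + alpha·2(TC/100)/(1+alpha) onto inhibitory and 1 + 2(TC/100)/(1+alpha)
onto excitatory targets (alpha = 1 + TCA/100); the fitted genotype is
(IC, TC, TCA) = (40, 30, 40)%. The LFP proxy is the summed magnitude of
all synaptic currents onto excitatory cells.

Key network-level results the package regenerates: the FHM1 network
fires less in response to contrast (WT/FHM1 contrast-gain slope ratio
≈ 1.9), its I/E ratio is shifted towards inhibition at every contrast,
and the three alterations contribute separably — TC raises both
population rates (inhibitory more, due to TCA), IC raises both, TCA
lowers both.

## Worked example

`examples/01_simulate_network.py` builds a reduced network (1250 neurons,
recurrent conductances scaled to preserve the full model's mean drive)
and compares genotypes, averaging five repetitions per condition:

```
WT    K=pre   exc  0.91 sp/s  inh  2.47 sp/s  I/E 0.677
WT    K=90    exc  1.05 sp/s  inh  2.84 sp/s  I/E 0.709
FHM1  K=pre   exc  1.19 sp/s  inh  4.93 sp/s  I/E 0.839
FHM1  K=90    exc  1.20 sp/s  inh  5.21 sp/s  I/E 0.848
```

Inhibitory neurons fire faster than excitatory ones in both genotypes;
FHM1 roughly doubles the inhibitory baseline rate and raises the I/E
current ratio — the network sits in a more inhibited state, which is
what limits its contrast response: from blank to K = 90 the excitatory
rate rises ~15% in WT but stays flat in FHM1 in this example. The other
examples run the spectral pipeline (02), the full laminar analysis chain
on a synthetic recording (03), and the information-theoretic pipeline
(04).

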