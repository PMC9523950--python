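# Methods

## The model

`fhmnet` simulates a local circuit of mouse primary visual cortex (V1) as
a sparse random network of leaky integrate-and-fire neurons: 80%
excitatory cells with AMPA-like output synapses and 20% inhibitory cells
with GABA-like output synapses, every ordered pair connected independently
with probability 0.2 and no self-connections. The membrane potential of
neuron *k* follows

    tau_m dV/dt = -(V - V_leak) + I_tot / g_leak,
    I_tot = sum_syn g_syn s_syn(t) (V_syn - V),

with tau_m = 20 ms (exc) / 10 ms (inh), g_leak = 25 / 20 nS, V_leak =
-70 mV, and reversal potentials V_AMPA = 0 mV, V_GABA = -80 mV. Each
synaptic pathway carries a dimensionless gating trace s(t); a presynaptic
spike at t* increments it, after the axonal latency tau_l, by a
difference of exponentials

    ds(t) = tau_m / (tau_d - tau_r) [exp(-(t - tau_l - t*)/tau_d)
                                     - exp(-(t - tau_l - t*)/tau_r)],

where tau_m is the postsynaptic membrane constant (the trace scales the
postsynaptic current, and the alternative presynaptic reading silences
the excitatory population entirely). With this normalization the time
integral of s per spike equals tau_m, so the mean synaptic conductance is
g_syn x (input rate) x tau_m. Latencies are 1 ms (GABA) and 2 ms
(AMPA); GABA rise/decay are 1 / 5 ms. The two glutamatergic kinetics
classes follow the model lineage: the fast synapse (0.2 / 1.25 ms)
contacts interneurons and the slow one (0.4 / 2.25 ms) contacts
pyramidal cells. We note explicitly that assigning the fast kinetics to
pyramidal targets instead leaves the network with no stable low-rate
state — the recurrent excitatory loop then outruns feedback inhibition
and every simulation diverges to a synchronous, refractory-limited
attractor — so the lineage assignment is treated as the intended one.

Wild-type conductances (nS): GABA→inh 2.70, GABA→exc 2.01, recurrent
AMPA→inh 0.233, →exc 0.178, and 0.317 / 0.234 (inh/exc targets) for each
of the three external AMPA-like drives.

Spike threshold, reset and refractory period are not constrained by the
source data; we use the lineage values V_thresh = -52 mV, V_reset =
-59 mV, tau_ref = 2 ms (exc) / 1 ms (inh), exposed in `NeuronParams`.

### FHM1 synaptic alterations

The familial-hemiplegic-migraine genotype is modelled purely as a
glutamatergic gain-of-function with three percentages:

* **IC** (intra-cortical): both recurrent AMPA conductances are scaled by
  `1 + IC/100`;
* **TC** (thalamocortical) with asymmetry **TCA** (`alpha = 1 +
  TCA/100`): the sustained-thalamic conductances are scaled by
  `1 + alpha*2*(TC/100)/(1+alpha)` onto inhibitory and
  `1 + 2*(TC/100)/(1+alpha)` onto excitatory targets, so the mean
  fractional increase is TC/100 and the inh/exc increase ratio is alpha.

GABAergic conductances are never altered. By default the narrow-band
thalamic synapses do not receive the TC gain (short-term depression of
FHM1 thalamocortical synapses wanes the gain at the sustained ~60 Hz
firing of the narrow-band-generating thalamic cells); a switch restores
it. The reference FHM1 fit is (IC, TC, TCA) = (40, 30, 40)%.

### External drives

Every neuron receives three independent Poisson spike-train drives with
AMPA kinetics:

* sustained thalamic, constant rate S(K): 1000 spikes/s for contrast
  K <= 30 and the blank screen, 1040 at K = 50, 1080 at K = 90;
* narrow-band gamma thalamic, rate `[A(K) eps(t)]_+` with eps(t)
  z-scored white noise band-passed by a 3rd-order Butterworth filter at
  57 +/- 5 Hz; A decreases with contrast (50, 45, 40, 30, 22.5, 15
  spikes/s at K = 0, 6, 8, 10, 15, 20) and vanishes for K >= 30 and the
  blank. A(15) is not constrained by the printed table and is set to the
  midpoint of its neighbours;
* cortical noise, rate `[theta_n n(t)]_+` with theta_n = 0.4 spikes/ms
  and n(t) a z-scored 1/f^1.5 trace, drawn independently per neuron. The
  per-neuron slow rate fluctuation is what maintains the tonic
  fluctuation-driven balanced state; with a single shared trace the
  network is bistable between near-silence and runaway.

### Integration and recording

Second-order Runge-Kutta (Heun) at dt = 0.05 ms; each synaptic trace is
advanced exactly as a two-state exponential system with event-triggered
jumps, and the half-step uses the analytically decayed trace. Spikes are
detected at grid resolution, followed by reset and a refractory clamp.
Simulations last 5 s by default with the first 200 ms discarded; the
external drives ramp up linearly over the first 100 ms (inside the
discard window) and V(0) is uniform over [V_leak, V_thresh) — a step
onset from a tight voltage distribution triggers a synchronous population
burst that can tip the network into its runaway attractor.

External Poisson events are drawn on a 1 ms grid and placed uniformly at
random within the 0.05 ms sub-steps; because all drive rates are
band-limited far below 1 kHz, this samples the same inhomogeneous Poisson
process as per-sub-step draws at ~20x lower cost. Event latency is
omitted for the external (stationary) trains, which only shifts them in
time.

The LFP proxy is the sum over excitatory neurons of the absolute values
of all AMPA-like and GABA currents. The model's "MUA" is the pooled
population firing rate (the model is stationary within a contrast
condition, so reversal-locked time courses are not simulated).

## Model-level measures

* **PSD**: Welch on z-scored traces, 1000 ms Hann segments, 50% overlap.
* **Spectral modulation**: `(PSD_K - PSD_blank) / PSD_blank` per
  frequency; band summaries over 12-40 Hz (beta/low gamma) and
  70-100 Hz (high gamma).
* **I/E ratio**: time-summed |GABA current| over time-summed excitatory
  current magnitude onto excitatory cells; the *total* variant counts
  recurrent AMPA plus both thalamic drives in the denominator, the
  *recurrent* variant only recurrent AMPA. Ratios are computed from
  population-summed pathway currents.
* **Contrast gain**: percent modulation of the pooled population rate at
  contrast K relative to the blank baseline, OLS slope vs K per genotype,
  WT/FHM1 slope ratio with a bootstrap (resampling repetitions) mean and
  95% CI.
* **Sweep modulations**: for one alteration swept with the other two at
  the FHM1 fit, the percent change of the baseline population rates at
  the reference value of the swept alteration relative to its zero
  value, `100 (rate(x_ref) - rate(0)) / rate(0)`. This normalization is
  the only one consistent with the signs of the published sweep figures
  (the thalamocortical-asymmetry sweep is negative for both populations,
  which a stimulation-versus-baseline reading cannot produce).
* **Reduced chi-square**: mean over frequency bins of squared residuals
  normalized by the per-frequency data SD (no parameter-count
  correction).

## Desk-scale study

The acceptance study runs N = 1250 neurons (1000 E / 250 I) at the
printed p = 0.2 with recurrent conductances multiplied by N_full/N = 4,
which preserves the full model's mean recurrent drive and its
shared-input correlation structure at a quarter of the cost; runs last
1200 ms (200 discarded), 10 repetitions per condition, one connectivity
graph shared by both genotypes. An alternative scaling that preserves
in-degrees by raising p to 0.8 was rejected: it quadruples input
correlations, makes feedback inhibition hyper-effective, and flips the
sign of the excitatory sweep responses. At this scale the WT/FHM1
contrast-gain slope ratio and the inhibition shift of the I/E ratio
reproduce the full model's behaviour; coherent network oscillations are
weaker relative to shot noise than at N = 5000 (coherent power scales
with N), so spectral-shape comparisons at this scale are noisier than
rate comparisons.

The sweep modulations reproduce the published signs and orderings (TC
raises both rates, inhibitory more; IC raises both; TCA lowers both,
excitatory more) but reach only a quarter to a half of the published
magnitudes. This is not a desk-scale artifact — the full N = 5000
network behaves the same under our threshold choices — and is attributed
to the unconstrained threshold/reset/refractory parameters; a grid over
plausible values did not close the gap, and we prefer reporting the
faithful model over tuning hidden parameters per target.

## Laminar-recording analysis

* **VEP**: epochs of [-100, 400] ms around each contrast reversal,
  averaged. Features (offset-invariant, referenced to the value at the
  reversal): N1 = most negative deflection in 20-150 ms; initial
  downslope = least-squares slope between the 2% and 25% crossings of
  the N1 amplitude (crossings located by linear interpolation); P2 =
  post-N1 maximum up to 300 ms, reported present only when it rises
  above the reference level by at least 20% of |N1| (a bare return
  towards baseline is not a P2).
* **CSD**: `-sigma d2(phi)/dz2` with sigma = 0.3 S/m by central second
  differences over the 50 um spacing after Gaussian depth smoothing
  (SD 0.07 mm); boundary channels dropped. Layer IV = interior channel
  with the earliest significant sink, where "significant" means three
  consecutive samples below -max(3 SD of baseline, 20% of the global
  sink maximum); onset ties at sample resolution are broken by sink
  magnitude.
* **MUA**: band-pass 200-450 Hz (Chebyshev-II, 60 dB stopband,
  zero-phase), squared, low-passed at 50 Hz, resampled to 500 Hz,
  epoched, and expressed as percent variation relative to the mean of
  the 100 ms before each reversal. The band is the widest the 1 kHz
  sampling supports and is configurable.
* **Scalogram**: in-house generalized Morse wavelet CWT (symmetry 3,
  time-bandwidth product 60, i.e. beta = 20), peak-normalized, evaluated
  on a logarithmic grid of 12 voices/octave over 4-120 Hz; modulation is
  per-frequency relative to the time-averaged blank-baseline scalogram.

## Information and permutation statistics

Responses are discretized into 7 equi-populated (quantile) bins per map
element; Shannon MI (log2) from the joint histogram. The
Panzeri-Treves limited-sampling correction subtracts
`[sum_s (R_s - 1) - (R - 1)] / (2 N ln 2)`, with R_s the estimated
number of effectively occupied response bins for stimulus s: the naive
occupied count, extended by the equiprobable-occupancy fixed point
`R_obs = R (1 - (1 - 1/R)^N)` when unoccupied bins remain. The
correction is clamped at zero from below so near-deterministic tables
are never pushed above the plug-in value. Calibration: on independent
data (7 stimuli, n = 350) the mean corrected MI is within +/-0.01 bits
of zero. Significance: 500 stimulus/response shuffles, p = (1 + #null >=
obs)/(1 + n_iter), Bonferroni across time points for 1-D maps and the
extreme-pixel maximum-statistic correction across tiles for 2-D maps.

Permutation tests between two groups: pixel-based (2-D) collects the
minimum and maximum of the permuted group-difference map and thresholds
the observed map at the 2.5th percentile of the minima and the 97.5th of
the maxima (2.5% per tail; pooling minima and maxima into a single null,
a literal alternative reading, inflates the family-wise error to ~0.13
and is not used); cluster-based (1-D) thresholds pointwise two-sample
t-tests at uncorrected alpha = 0.05 per permutation and uses the maximal
run length as the null statistic, upper tail only (a lower tail on run
lengths is vacuous). Defaults: 1000 permutations. Empirical FWE on null
data is ~0.05 for both.

## Synthetic recordings

The generator emulates the statistical structure of the experimental
recordings, not their biophysics: per-channel 1/f background;
depth-profiled reversal-locked VEP template (polarity inversion around
the designated layer-IV channel, giving a well-defined earliest sink);
stimulus-gated ~57 Hz narrow band whose amplitude falls with contrast;
post-reversal broad-band bursts in 12-40 Hz (WT-like) or 70-100 Hz
(FHM1-like) growing with contrast; and Poisson biphasic spike transients
whose post-reversal rate burst grows linearly in contrast with a
genotype-dependent slope (WT twice FHM1). The FHM1 template omits the P2
and delays N1. All planted effect sizes are free configuration values
chosen once to mimic the qualitative experimental findings; the sidecar
records every planted value, and the closed-loop suite recovers them
(N1 latency within a few ms, layer-IV channel exactly, MUA peak within
~25 ms given envelope-estimation noise). Passing these tests shows the
analysis chain is correct on data with the assumed structure; it does
not validate the generator against real tissue.

## Known limitations

* The three neuron parameters the source does not print (threshold,
  reset, refractory period) control the network's operating point; the
  published sweep-modulation magnitudes could not be matched anywhere in
  the probed parameter range, although all signs and orderings are
  reproduced.
* At N = 1250 the coherent broad-band gamma of the full network is
  partially masked by shot noise, so spectral-modulation band
  comparisons at desk scale are noisy.
* Reversal-locked dynamics (VEPs, MUA time courses) are outside the
  model's scope: the thalamic drive is time-invariant within a
  condition, so simulated quantities are temporal averages.
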