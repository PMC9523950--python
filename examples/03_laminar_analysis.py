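"""Full laminar analysis chain on a synthetic recording.

Generates a synthetic 16-channel contrast-reversal recording with known
planted structure, then runs the analysis stack: VEP averaging and
features, CSD with layer-IV identification, normalized MUA, and the Morse
scalogram modulation.
"""

import numpy as np

from fhmnet import (SynthConfig, csd, generate_recording, mua_extract,
                    scalogram_modulation, vep_average, vep_features)

cfg = SynthConfig(genotype="wt", n_reversals=30, seed=3)
rec, planted = generate_recording(cfg, K=20)
print("planted:", {k: planted[k] for k in
                   ("n1_amp_mv", "n1_latency_ms", "layer4_channel",
                    "mua_peak_ms")})

ch = planted["layer4_channel"]
t, vep = vep_average(rec, ch)
feat = vep_features(t, vep)
print(f"VEP:  N1 {feat.n1_amp:.3f} mV at {feat.n1_latency:.0f} ms, "
      f"downslope {feat.downslope:.1f} mV/s, P2 present: {feat.has_p2}")

prof = csd(rec)
print(f"CSD:  earliest sink (layer IV) at channel {prof.layer4_channel}")

tm, mua = mua_extract(rec.data[ch], rec.fs, rec.reversal_times)
print(f"MUA:  peak {mua.max():.0f}% at {tm[np.argmax(mua)]:.0f} ms "
      "after the reversal")

sm = scalogram_modulation(rec, ch)
band = (sm.freqs >= 52) & (sm.freqs <= 62)
print(f"Scalogram: narrow-gamma modulation {np.nanmean(sm.mod[band]):.1f} "
      "(vs blank baseline)")

print()
print("Each number recovers a planted property of the synthetic recording:")
print("the N1 deflection and its latency, the depth of the current sink,")
print("the post-reversal firing burst, and the ~57 Hz narrow-band gamma.")
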