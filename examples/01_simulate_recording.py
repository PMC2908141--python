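"""Render one synthetic control-basal slice and inspect what was planted.

Generates a 50-s, 64-electrode recording with the control-basal activity
preset (15 active electrodes, 5 units each, 6.08 Hz aggregate), then prints
the planted ground truth the analysis stages will later be scored against.
"""

import numpy as np

import vhmea

geometry = vhmea.ArrayGeometry.default()
preset = vhmea.build_preset("control", "basal")
segment, truth = vhmea.render_recording(
    geometry, preset, vhmea.NoiseModel(), seed=1, slice_id="demo",
)

counts = truth.counts_per_electrode()
active = [e for e in range(64) if truth.active[e]]
print(f"segment: {segment.samples.shape[0]} electrodes x {segment.n_samples} samples "
      f"({segment.duration:.0f} s @ {segment.fs:.0f} Hz), condition {segment.condition}")
print(f"planted active electrodes: {len(active)} -> {active}")
print(f"total planted spikes: {truth.total_spikes()}")
rates = [sum(truth.rates[k] for k in truth.rates if k[0] == e) for e in active]
print(f"aggregate planted rate per active electrode: {np.mean(rates):.2f} Hz")
# Active electrodes carry >= 50 spikes per 50 s (the 1 Hz criterion);
# everything else stays below it by construction.
print("min planted count on active electrodes:",
      min(counts[e] for e in active))
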