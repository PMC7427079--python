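"""Render one synthetic cardiac cycle and inspect its ground truth.

The beat template carries the peak myocardial velocities (Am, Sm, Em in
cm/s) and the six-phase layout of the cycle.  The printed peaks are the
template amplitudes exactly, because the waveform is rendered on the
sampling grid without noise.
"""

import ctdikit as ck

params = ck.BeatTemplateParams(heart_rate=140, sm_amp=2.77, em_amp=3.55, am_amp=4.27)
t, v, truth = ck.simulate_beat(params, frame_rate=200.0)

print(f"one cycle at 140 bpm, 200 fps -> {v.size} samples ({t[-1]:.3f} s)")
print("phase boundaries (sample indices):")
for name, (s, e) in zip(
    ("atrial contraction", "pre-ejection", "ejection", "post-ejection",
     "rapid filling", "slow filling"),
    truth.phase_bounds,
):
    print(f"  {name:<18} [{s:3d}, {e:3d})")
print("ground-truth peaks (cm/s):", truth.peak_values)
print()
print("Sm is the systolic (ejection) peak, Em the early-diastolic filling")
print("peak and Am the atrial-contraction peak; Em/Am indexes diastolic")
print(f"function: {truth.peak_values['em'] / truth.peak_values['am']:.3f} here.")
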