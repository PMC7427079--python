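"""Analyze a noisy multi-beat velocity trace end to end.

Simulates a 4 s basal-view recording with measurement noise and beat
jitter, then runs the automated chain: orientation normalization, beat
detection, six-phase classification, fusion flagging, peak extraction
and averaging over all cycles.
"""

import ctdikit as ck

template = ck.BeatTemplateParams(heart_rate=143)
cfg = ck.TraceSimConfig(
    frame_rate=205.0, duration=4.0, orientation="basal",
    noise_sd=0.25, beat_jitter_cv=0.02, seed=7,
)
trace, truth = ck.simulate_trace(template, cfg)

summary, maps = ck.analyze_trace(trace)
print(f"trace: {trace.duration:.1f} s, {trace.orientation} view, "
      f"{trace.frame_rate:.0f} fps, noise {cfg.noise_sd} cm/s")
print(f"detected {summary.n_beats_total} cycles "
      f"(ground truth {truth.n_beats}), heart rate {summary.heart_rate:.1f} bpm")
print(f"Sm {summary.sm_mean:.2f}  Em {summary.em_mean:.2f}  "
      f"Am {summary.am_mean:.2f} cm/s   Em/Am {summary.em_am_ratio:.3f}")
print(f"(template truth: Sm {template.sm_amp}, Em {template.em_amp}, "
      f"Am {template.am_amp}, Em/Am {template.em_amp / template.am_amp:.3f})")
print()
print("The averaged peaks land within the noise of the template values;")
print("the basal view was sign-flipped automatically before analysis.")
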