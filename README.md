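# ctdikit

Automated analysis of fetal myocardial velocity traces from color tissue
Doppler imaging (cTDI), built around the assessment of fetal cardiac
function before and after intrauterine transfusion (IUT) for fetal
anemia.

cTDI records the velocity of the myocardium itself (not blood flow) at
the atrioventricular plane of the left ventricular wall (LV), the
interventricular septum (IVS) and the right ventricular wall (RV), at
~200 frames/s in an apical or basal four-chamber view.  Each cardiac
cycle shows a positive ejection wave and two negative diastolic waves,
giving three peak velocities per wall:

* **Sm** — peak velocity during ventricular ejection (systole),
* **Em** — peak velocity during rapid ventricular filling (early diastole),
* **Am** — peak velocity during atrial contraction (late diastole),

plus the diastolic index **Em/Am**.  At high fetal heart rates the E and
A waves merge (**E/A fusion**) and Em/Am cannot be measured.

The package implements the full analysis chain as a library:

* `ctdikit.simulate` — synthetic beat/trace/cohort generator with exact
  ground truth (raised-cosine wave morphology, six cardiac-cycle phases,
  physical E/A fusion at high rates, anemia-dependent velocity
  elevation, paired pre/post-transfusion shifts);
* `ctdikit.trace_io` — text trace dialect (header + TSV) and cohort
  metadata CSV;
* `ctdikit.events` — orientation normalization, beat detection from the
  trace's autocovariance, six-phase classification via a cross-beat
  consensus template, fusion flagging, cross-segment refinement;
* `ctdikit.metrics` — per-beat Am/Sm/Em extraction, fusion-omission
  rule, averaging over all cardiac cycles, noise-floor quality omission;
* `ctdikit.reference` — gestational-age z-scores
  `z = (x − mean(GA)) / SD(GA)`, multiples of the median (MoM) for
  hemoglobin and middle-cerebral-artery peak systolic velocity, and
  anemia grading (severe < 0.55 ≤ moderate < 0.65 ≤ mild < 0.84 ≤ none
  Hb MoM).  The packaged reference curves are **synthetic** stand-ins;
  supply your own YAML for clinical use;
* `ctdikit.stats` — mean z with 95% CI before IUT, Spearman correlations
  of z-scores with Hb/MCA-PSV MoM, paired Wilcoxon signed-rank tests of
  before vs after, outlier audit and study-style summary tables;
* `ctdikit.pipeline` / the `ctdikit` command — simulate → analyze →
  report over directories of trace files.

## Worked example

`examples/02_trace_analysis.py` simulates a 4 s basal-view recording
(205 fps, 0.25 cm/s noise, 2% beat jitter) and runs the automated chain:

```
trace: 4.0 s, basal view, 205 fps, noise 0.25 cm/s
detected 9 cycles (ground truth 9), heart rate 143.7 bpm
Sm 2.96  Em 3.72  Am 4.37 cm/s   Em/Am 0.852
(template truth: Sm 2.77, Em 3.55, Am 4.27, Em/Am 0.831)
```

All nine cardiac cycles are found, the basal sign flip is undone
automatically, and the averaged peak velocities land within the
measurement noise of the template's true amplitudes.  The other
examples show a single annotated beat (`01`), the fusion transition
across a 120→210 bpm sweep (`03`), and a full cohort with
before/after-transfusion statistics (`04`).

A shell workflow over files:

```sh
ctdikit simulate --out run --seed 1
ctdikit analyze  --out run
ctdikit report   --out run
```

writes traces, per-beat phase tables, segment summaries, the normalized
cohort and study-style tables/figures under `run/`.

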