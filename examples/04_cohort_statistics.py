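"""Simulate a transfusion cohort and reproduce the inferential stage.

Each fetus gets paired exams before and after an intrauterine
transfusion.  The generator imposes a hyperdynamic elevation of the
z-scores before transfusion, a negative dependence of Em on anemia
severity (1 - Hb MoM), and a post-transfusion decrease.  The pipeline
then recovers: mean z with 95% CI before transfusion, Spearman
correlations of z against Hb MoM, and paired Wilcoxon changes.
"""

import ctdikit as ck
from ctdikit.pipeline import analyze_exam
from ctdikit.stats import build_cohort_table, build_tables

ref = ck.default_reference()
cfg = ck.CohortSimConfig(n_fetuses=50, walls=("LV",), seed=1)
sim = ck.simulate_cohort(cfg, ref)

summaries = []
for exam_id, traces in sim.traces.items():
    s, _ = analyze_exam(traces, cross_segment=False)
    summaries.extend(s)

cohort = build_cohort_table(summaries, sim.records, ref)
tables = build_tables(cohort)

print("before-transfusion summary (LV):")
print(tables["before_summary"].round(3).to_string(index=False))
print()
print("paired before/after changes (LV):")
cols = ["variable", "z_median_delta", "z_iq_low", "z_iq_high", "z_p", "significant"]
print(tables["paired_changes"][cols].round(3).to_string(index=False))
print()
print("correlations of z-scores with Hb MoM / MCA PSV MoM before IUT:")
print(tables["correlations"].round(3).to_string(index=False))
print()
print("A significant positive mean z before transfusion reflects the")
print("hyperdynamic circulation of fetal anemia; negative median delta z")
print("with small Wilcoxon p reflects the post-transfusion decrease.")
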