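# SYNTHETIC gestational-age reference model for ctdikit.
#
# These curves are a synthetic stand-in with plausible magnitudes for
# fetal AV-plane myocardial velocities (cm/s), hemoglobin (g/L) and MCA
# peak systolic velocity (cm/s) between 18 and 38 weeks.  They are NOT
# published clinical reference ranges and must not be used clinically;
# supply your own coefficients in this schema to reproduce clinical use.
#
# Curves are polynomials in GA (weeks), coefficients in ascending order.
ga_support: [18.0, 38.0]
hb_median: [85.0, 1.56]          # g/L:  113 @ 18w, 130 @ 28.6w, 144 @ 38w
mca_psv_median: [8.4, 0.98]      # cm/s:  26 @ 18w,  36 @ 28.6w,  46 @ 38w
variables:
  Am:
    LV:  {mean: [0.0, 0.1336], sd: [1.46]}
    IVS: {mean: [0.0, 0.1311], sd: [1.01]}
    RV:  {mean: [0.0, 0.1976], sd: [1.46]}
  Sm:
    LV:  {mean: [0.0, 0.0836], sd: [1.11]}
    IVS: {mean: [0.0, 0.0871], sd: [0.68]}
    RV:  {mean: [0.0, 0.1161], sd: [1.14]}
  Em:
    LV:  {mean: [0.0, 0.1042], sd: [1.19]}
    IVS: {mean: [0.0, 0.1094], sd: [0.96]}
    RV:  {mean: [0.0, 0.1416], sd: [1.28]}
  EmAm:
    LV:  {mean: [0.687, 0.005], sd: [0.36]}
    IVS: {mean: [0.727, 0.005], sd: [0.28]}
    RV:  {mean: [0.597, 0.005], sd: [0.26]}
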