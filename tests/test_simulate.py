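"""Tests of the synthetic beat/trace/cohort generator and its ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctdikit as ck
from ctdikit.simulate import DegenerateSamplingError


class TestSimulateBeat:
    def test_null_template_gives_zero_waveform(self):
        params = ck.BeatTemplateParams(sm_amp=0, em_amp=0, am_amp=0, iso_amp=0)
        _, v, truth = ck.simulate_beat(params, 200.0)
        assert np.all(v == 0.0)
        assert truth.peak_values == {"am": 0.0, "sm": 0.0, "em": 0.0}

    def test_cycle_length_arithmetic(self):
        _, v, _ = ck.simulate_beat(ck.BeatTemplateParams(heart_rate=140), 200.0)
        assert v.size == round(200 * 60 / 140) == 86

    def test_realistic_amplitudes_render_exactly(self):
        params = ck.BeatTemplateParams(sm_amp=2.77, em_amp=3.55, am_amp=4.27)
        _, v, truth = ck.simulate_beat(params, 200.0)
        assert v.max() == 2.77
        # E and A are negative in canonical orientation; A is the deepest
        assert v.min() == -4.27
        for label, value in truth.peak_values.items():
            assert v[truth.peak_samples[label]] == pytest.approx(
                value if label == "sm" else -value, abs=0
            )

    def test_degenerate_sampling_raises(self):
        params = ck.BeatTemplateParams(
            phase_fractions=(0.2, 0.05, 0.45, 0.05, 0.004, 0.246)
        )
        with pytest.raises(DegenerateSamplingError):
            ck.simulate_beat(params, 100.0)

    @pytest.mark.parametrize("hr", [100, 140, 170, 200])
    def test_phase_durations_tile_cycle(self, hr):
        _, v, truth = ck.simulate_beat(ck.BeatTemplateParams(), 200.0, heart_rate=hr)
        spans = truth.phase_bounds
        assert spans[0][0] == 0 and spans[-1][1] == v.size
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 == s1  # contiguous, disjoint


class TestSimulateTrace:
    @pytest.mark.parametrize("duration,hr,expected", [(4.0, 140, 9), (10.0, 140, 23)])
    def test_complete_beat_count(self, duration, hr, expected):
        tr, truth = ck.simulate_trace(
            ck.BeatTemplateParams(heart_rate=hr), ck.TraceSimConfig(duration=duration)
        )
        assert truth.n_beats == expected == int(duration * hr // 60)

    def test_seeded_reproducibility(self):
        cfg = ck.TraceSimConfig(noise_sd=0.3, beat_jitter_cv=0.03, seed=42)
        t1, g1 = ck.simulate_trace(ck.BeatTemplateParams(), cfg)
        t2, g2 = ck.simulate_trace(ck.BeatTemplateParams(), cfg)
        assert np.array_equal(t1.samples, t2.samples)
        assert [b.phase_bounds for b in g1.beats] == [b.phase_bounds for b in g2.beats]
        t3, _ = ck.simulate_trace(
            ck.BeatTemplateParams(), ck.TraceSimConfig(noise_sd=0.3, seed=43)
        )
        assert not np.array_equal(t1.samples, t3.samples)

    def test_basal_is_exact_negation_of_apical(self):
        kw = dict(noise_sd=0.25, beat_jitter_cv=0.02, seed=7)
        ta, _ = ck.simulate_trace(
            ck.BeatTemplateParams(), ck.TraceSimConfig(orientation="apical", **kw)
        )
        tb, _ = ck.simulate_trace(
            ck.BeatTemplateParams(), ck.TraceSimConfig(orientation="basal", **kw)
        )
        assert np.array_equal(ta.samples, -tb.samples)

    def test_duration_must_cover_two_cycles(self):
        with pytest.raises(ValueError):
            ck.simulate_trace(
                ck.BeatTemplateParams(heart_rate=80), ck.TraceSimConfig(duration=1.0)
            )

    def test_jittered_phases_still_tile(self):
        _, truth = ck.simulate_trace(
            ck.BeatTemplateParams(), ck.TraceSimConfig(beat_jitter_cv=0.05, seed=3)
        )
        lengths = {b.end - b.start for b in truth.beats}
        assert len(lengths) > 1  # jitter did vary the cycle length
        for b in truth.beats:
            assert b.phase_bounds[0][0] == b.start
            assert b.phase_bounds[-1][1] == b.end
            for (s0, e0), (s1, e1) in zip(b.phase_bounds, b.phase_bounds[1:]):
                assert e0 == s1


def _diastolic_negative_runs(v, lo, hi, depth_frac=0.10):
    """Independent fusion oracle: count negative runs deeper than a
    fraction of the deepest diastolic excursion."""
    seg = v[lo:hi]
    depth = -seg.min()
    below = seg < -depth_frac * depth
    runs = 0
    prev = False
    for flag in below:
        if flag and not prev:
            runs += 1
        prev = flag
    return runs


class TestFusion:
    def test_high_rate_fuses_all_beats(self, template):
        tr, truth = ck.simulate_fused_trace(
            template, ck.TraceSimConfig(duration=6.0), 200.0
        )
        assert all(b.fused for b in truth.beats)
        # oracle: the rendered diastole holds a single merged negative run
        for b0, b1 in zip(truth.beats, truth.beats[1:]):
            runs = _diastolic_negative_runs(
                tr.samples, b0.phase_bounds[4][0], b1.phase_bounds[0][1]
            )
            assert runs == 1

    def test_low_rate_never_fuses(self, template):
        tr, truth = ck.simulate_fused_trace(
            template, ck.TraceSimConfig(duration=6.0), 120.0
        )
        assert not any(b.fused for b in truth.beats)
        for b0, b1 in zip(truth.beats, truth.beats[1:]):
            runs = _diastolic_negative_runs(
                tr.samples, b0.phase_bounds[4][0], b1.phase_bounds[0][1]
            )
            assert runs == 2

    def test_narrow_waves_never_fuse(self):
        params = ck.BeatTemplateParams(wave_width_frac=0.1)
        _, truth = ck.simulate_fused_trace(
            params, ck.TraceSimConfig(duration=6.0), 210.0
        )
        assert not any(b.fused for b in truth.beats)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    hr=st.floats(100, 180),
    f_ej=st.floats(0.25, 0.4),
    f_rf=st.floats(0.12, 0.25),
)
def test_phase_fraction_property(hr, f_ej, f_rf):
    """Phase durations always sum to the cycle length, for arbitrary templates."""
    rest = 1.0 - 0.05 - 0.05 - f_ej - f_rf
    fr = (0.4 * rest, 0.05, f_ej, 0.05, f_rf, 0.6 * rest)
    fr = tuple(f / sum(fr) for f in fr)
    params = ck.BeatTemplateParams(heart_rate=hr, phase_fractions=fr)
    _, v, truth = ck.simulate_beat(params, 200.0)
    total = sum(e - s for s, e in truth.phase_bounds)
    assert total == v.size


class TestSimulateCohort:
    def test_no_effect_gives_near_zero_correlation(self, ref):
        cfg = ck.CohortSimConfig(
            n_fetuses=300, slope_em_z_per_mom=0.0, walls=("LV",), seed=5
        )
        sim = ck.simulate_cohort(cfg, ref, render_traces=False)
        before = sim.truth[sim.truth.timing == "before"]
        r = ck.spearman_corr(before.hb_mom, before.z_Em_LV)
        assert abs(r.estimate) < 0.15

    def test_copula_mode_hits_target_spearman(self, ref):
        cfg = ck.CohortSimConfig(
            n_fetuses=800, target_rho_em_am=-0.8, walls=("LV",), seed=6
        )
        sim = ck.simulate_cohort(cfg, ref, render_traces=False)
        before = sim.truth[sim.truth.timing == "before"]
        r = ck.spearman_corr(before.hb_mom, before.z_EmAm_LV)
        assert r.estimate == pytest.approx(-0.8, abs=0.05)

    def test_clipping_recorded(self, ref):
        cfg = ck.CohortSimConfig(
            n_fetuses=3, base_z={"Am": -30.0, "Sm": 0, "Em": 0}, walls=("LV",), seed=0
        )
        sim = ck.simulate_cohort(cfg, ref, render_traces=False)
        assert sim.truth.clipped.all()

    def test_deterministic_truth_table(self, ref):
        cfg = ck.CohortSimConfig(n_fetuses=5, seed=9, walls=("LV",))
        a = ck.simulate_cohort(cfg, ref, render_traces=False).truth
        b = ck.simulate_cohort(cfg, ref, render_traces=False).truth
        assert a.equals(b)

    def test_paired_shift_applied(self, ref):
        cfg = ck.CohortSimConfig(
            n_fetuses=400,
            post_iut_delta_z={"Am": -0.6},
            walls=("LV",),
            seed=2,
        )
        sim = ck.simulate_cohort(cfg, ref, render_traces=False)
        t = sim.truth.pivot_table(index="fetus_id", columns="timing", values="z_Am_LV")
        d = (t["after"] - t["before"]).to_numpy()
        assert np.mean(d) == pytest.approx(-0.6, abs=0.15)
        assert np.std(d) == pytest.approx(1.0, rel=0.2)
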