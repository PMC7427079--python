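"""Event detection: orientation, beats, phase classification, fusion."""

import logging

import numpy as np
import pytest

import ctdikit as ck
from ctdikit.events import (
    InsufficientQualityError,
    NoBeatsError,
    OrientationError,
    _two_separated_minima,
)
from conftest import boundary_errors


def _trace(hr=140, duration=10.0, noise=0.0, jitter=0.0, seed=2, orientation="apical"):
    return ck.simulate_trace(
        ck.BeatTemplateParams(heart_rate=hr),
        ck.TraceSimConfig(
            duration=duration,
            noise_sd=noise,
            beat_jitter_cv=jitter,
            seed=seed,
            orientation=orientation,
        ),
    )


class TestNormalizeOrientation:
    def test_apical_unchanged(self):
        tr, _ = _trace()
        canon, orient = ck.normalize_orientation(tr)
        assert orient == "apical"
        np.testing.assert_array_equal(canon.samples, tr.samples)

    def test_basal_negated_matches_apical_twin(self):
        ta, _ = _trace(noise=0.2, seed=3, orientation="apical")
        tb, _ = _trace(noise=0.2, seed=3, orientation="basal")
        ca, _ = ck.normalize_orientation(ta)
        cb, _ = ck.normalize_orientation(tb)
        np.testing.assert_array_equal(ca.samples, cb.samples)

    @pytest.mark.parametrize("orientation", ["apical", "basal"])
    def test_unknown_orientation_inferred(self, orientation):
        tr, _ = _trace(noise=0.2, seed=4, orientation=orientation)
        unknown = tr.copy_with(orientation="unknown")
        canon, detected = ck.normalize_orientation(unknown)
        assert detected == orientation
        reference, _ = ck.normalize_orientation(tr)
        np.testing.assert_array_equal(canon.samples, reference.samples)

    def test_zero_trace_unresolved(self):
        tr = ck.VelocityTrace("e", "LV", "unknown", 200.0, np.zeros(800))
        with pytest.raises(OrientationError):
            ck.normalize_orientation(tr)

    def test_short_trace_rejected(self):
        tr = ck.VelocityTrace("e", "LV", "apical", 200.0, np.zeros(100))
        with pytest.raises(OrientationError):
            ck.normalize_orientation(tr)


class TestDetectBeats:
    def test_noiseless_cycle_count_and_bounds(self):
        tr, truth = _trace(hr=140, duration=10.0)
        bounds, hr = ck.detect_beats(tr)
        assert len(bounds) == truth.n_beats == 23
        for (s, e), b in zip(bounds, truth.beats):
            assert abs(s - b.start) <= 1
            assert abs(e - b.end) <= 1
        assert hr == pytest.approx(140, abs=0.6)

    def test_constant_trace_raises(self):
        tr = ck.VelocityTrace("e", "LV", "apical", 200.0, np.ones(2000))
        with pytest.raises(NoBeatsError):
            ck.detect_beats(tr)

    def test_heart_rate_accurate_under_noise(self):
        errs = []
        for seed in range(10):
            tr, _ = _trace(duration=4.0, noise=0.277, seed=seed)
            _, hr = ck.detect_beats(tr)
            errs.append(abs(hr - 140))
        assert max(errs) <= 2.0


class TestClassifyPhases:
    @pytest.mark.parametrize("hr", [120, 145, 170])
    def test_noiseless_boundaries_within_one_sample(self, hr):
        tr, truth = _trace(hr=hr)
        bounds, _ = ck.detect_beats(tr)
        maps = ck.classify_phases(tr, bounds)
        assert boundary_errors(truth, maps).max() <= 1

    def test_tiling_invariant(self):
        tr, _ = _trace(noise=0.3, jitter=0.02, duration=4.0)
        bounds, _ = ck.detect_beats(tr)
        for m in ck.classify_phases(tr, bounds):
            assert m.phase_bounds[0][0] == m.start
            assert m.phase_bounds[-1][1] == m.end
            for (s0, e0), (s1, e1) in zip(m.phase_bounds, m.phase_bounds[1:]):
                assert e0 == s1

    def test_consensus_idempotent_for_identical_beats(self):
        """With identical beats the template equals any single beat, so all
        per-beat phase layouts are identical (up to the cycle offset)."""
        tr, _ = _trace(duration=6.0)
        bounds, _ = ck.detect_beats(tr)
        maps = ck.classify_phases(tr, bounds)
        layouts = {
            tuple(s - m.start for s, _ in m.phase_bounds) for m in maps
        }
        assert len(layouts) == 1
        assert all(m.quality == pytest.approx(1.0) for m in maps)

    def test_duplicating_beats_leaves_consensus_unchanged(self):
        """A longer trace of the same identical beats yields the same
        within-beat boundaries: the median consensus is unaffected."""
        short, _ = _trace(duration=4.0)
        long, _ = _trace(duration=8.0)
        m_short = ck.classify_phases(short, ck.detect_beats(short)[0])
        m_long = ck.classify_phases(long, ck.detect_beats(long)[0])
        rel = lambda m: tuple(s - m.start for s, _ in m.phase_bounds)
        assert rel(m_short[1]) == rel(m_long[1])

    def test_noisy_boundaries_mostly_within_three_samples(self):
        errs = []
        for seed in range(8):
            tr, truth = _trace(
                duration=4.5, noise=0.15 * 2.77, jitter=0.02, seed=100 + seed
            )
            bounds, _ = ck.detect_beats(tr)
            maps = ck.classify_phases(tr, bounds)
            errs.extend(boundary_errors(truth, maps))
        errs = np.asarray(errs)
        assert (errs <= 3).mean() >= 0.90

    def test_too_few_beats_rejected(self):
        tr, _ = _trace(duration=4.0)
        with pytest.raises(InsufficientQualityError):
            ck.classify_phases(tr, ck.detect_beats(tr)[0][:1])


class TestDetectFusion:
    def _flags(self, hr):
        tr, _ = ck.simulate_fused_trace(
            ck.BeatTemplateParams(), ck.TraceSimConfig(duration=6.0), hr
        )
        bounds, _ = ck.detect_beats(tr)
        maps = ck.detect_fusion(ck.classify_phases(tr, bounds), tr)
        return [m.fused for m in maps]

    def test_high_rate_all_fused(self):
        assert all(self._flags(200))

    def test_low_rate_none_fused(self):
        assert not any(self._flags(120))

    def test_impulses_with_zero_gap_not_fused(self):
        seg = np.zeros(60)
        seg[10:15] = -3.0
        seg[45:50] = -4.0
        assert _two_separated_minima(seg, 0.10)

    def test_single_trough_is_fused(self):
        x = np.linspace(-1, 1, 80)
        seg = -4.0 * np.exp(-(x**2) / 0.1)
        assert not _two_separated_minima(seg, 0.10)


class TestCrossSegmentRefine:
    def _exam(self, seed=5, noise=0.0):
        traces, maps = {}, {}
        for wall in ("LV", "IVS", "RV"):
            tr, _ = ck.simulate_trace(
                ck.BeatTemplateParams(),
                ck.TraceSimConfig(duration=5.0, seed=seed, noise_sd=noise),
            )
            tr = tr.copy_with(wall=wall)
            bounds, _ = ck.detect_beats(tr)
            traces[wall] = tr
            maps[wall] = ck.detect_fusion(ck.classify_phases(tr, bounds), tr)
        return traces, maps

    def test_identical_walls_unchanged(self):
        traces, maps = self._exam()
        refined = ck.cross_segment_refine(traces, maps)
        for wall in maps:
            assert [m.cycle_bounds for m in refined[wall]] == [
                m.cycle_bounds for m in maps[wall]
            ]
            assert [m.phase_bounds for m in refined[wall]] == [
                m.phase_bounds for m in maps[wall]
            ]

    def test_median_overrides_single_perturbed_wall(self):
        from dataclasses import replace

        traces, maps = self._exam()
        perturbed = [
            replace(m, cycle_bounds=(m.start + 3, m.end + 3)) for m in maps["RV"]
        ]
        maps2 = {**maps, "RV": perturbed}
        refined = ck.cross_segment_refine(traces, maps2)
        for wall in ("LV", "IVS", "RV"):
            assert [m.cycle_bounds for m in refined[wall]] == [
                m.cycle_bounds for m in maps["LV"]
            ]

    def test_mismatched_beat_counts_skips_with_warning(self, caplog):
        traces, maps = self._exam()
        maps2 = {**maps, "RV": maps["RV"][:-1]}
        with caplog.at_level(logging.WARNING, logger="ctdikit.events"):
            refined = ck.cross_segment_refine(traces, maps2)
        assert refined == maps2
        assert any("skipped" in r.message for r in caplog.records)
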