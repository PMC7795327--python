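"""Burr duration models, negative-event generation, and excerpting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from arslab.events import (
    OTHER_CRACKLE_BURR,
    OTHER_WHEEZE_BURR,
    BurrParams,
    ExcerptPolicy,
    burr_cdf,
    burr_mode,
    burr_pdf,
    excerpt_event,
    generate_fixed_rge,
    generate_variable_rge,
    sample_durations,
)
from arslab.exceptions import GenerationError, ValidationError
from arslab.io_rsd import AnnotatedEvent

BOTH_MODELS = [OTHER_CRACKLE_BURR, OTHER_WHEEZE_BURR]


class TestBurrDensity:
    @pytest.mark.parametrize("p", BOTH_MODELS, ids=["otherCrackle", "otherWheeze"])
    def test_integrates_to_one_by_quadrature(self, p):
        integral, err = quad(lambda x: burr_pdf(x, p), 1e-12, np.inf, limit=200)
        assert abs(integral - 1.0) < 1e-6

    @pytest.mark.parametrize("p", BOTH_MODELS, ids=["otherCrackle", "otherWheeze"])
    def test_nonnegative_on_sampled_points(self, p):
        x = np.geomspace(1e-6, 50.0, 500)
        assert np.all(burr_pdf(x, p) >= 0)

    @pytest.mark.parametrize("p", BOTH_MODELS, ids=["otherCrackle", "otherWheeze"])
    def test_grid_argmax_matches_closed_form_mode(self, p):
        """Grid-search oracle for the mode alpha*((c-1)/(k*c+1))**(1/c)."""
        grid = np.linspace(1e-4, 2.0, 200_001)
        numeric = grid[np.argmax(burr_pdf(grid, p))]
        assert abs(numeric - burr_mode(p)) < 1e-4

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            BurrParams(alpha=-1.0, c=1.0, k=1.0)
        with pytest.raises(ValidationError):
            BurrParams(alpha=1.0, c=1.0, k=1.0, lower=0.5, upper=0.4)
        with pytest.raises(ValidationError):
            burr_pdf(-0.1, OTHER_WHEEZE_BURR)


class TestSampleDurations:
    def test_crackle_truncation_respected(self):
        x = sample_durations(OTHER_CRACKLE_BURR, 100_000, seed=0)
        assert x.max() <= 0.1
        assert x.min() > 0.0

    def test_wheeze_truncation_respected(self):
        x = sample_durations(OTHER_WHEEZE_BURR, 100_000, seed=0)
        assert x.max() <= 2.0
        assert x.min() > 0.1

    def test_empty_draw(self):
        assert sample_durations(OTHER_WHEEZE_BURR, 0, seed=0).size == 0

    def test_reproducible(self):
        a = sample_durations(OTHER_WHEEZE_BURR, 1000, seed=7)
        b = sample_durations(OTHER_WHEEZE_BURR, 1000, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("p", BOTH_MODELS, ids=["otherCrackle", "otherWheeze"])
    def test_mean_matches_quadrature_of_truncated_density(self, p):
        """Quadrature oracle: empirical mean within 3 SEs of the analytic mean."""
        mass, _ = quad(lambda x: burr_pdf(x, p), p.lower + 1e-12, p.upper, limit=200)
        m1, _ = quad(lambda x: x * burr_pdf(x, p), p.lower + 1e-12, p.upper, limit=200)
        m2, _ = quad(lambda x: x * x * burr_pdf(x, p), p.lower + 1e-12, p.upper, limit=200)
        mean = m1 / mass
        var = m2 / mass - mean**2
        x = sample_durations(p, 100_000, seed=11)
        se = np.sqrt(var / x.size)
        assert abs(x.mean() - mean) < 3 * se

    @pytest.mark.parametrize("p", BOTH_MODELS, ids=["otherCrackle", "otherWheeze"])
    def test_ks_against_truncated_cdf(self, p):
        lo, hi = float(burr_cdf(p.lower, p)), float(burr_cdf(p.upper, p))
        x = sample_durations(p, 100_000, seed=5)
        res = kstest(x, lambda v: (burr_cdf(v, p) - lo) / (hi - lo))
        assert res.statistic < 0.01

    def test_vanishing_acceptance_window_rejected(self):
        narrow = BurrParams(alpha=0.199, c=7.6698, k=0.3146, lower=0.0, upper=1e-9)
        with pytest.raises(GenerationError):
            sample_durations(narrow, 10, seed=0)


class TestRGE:
    def test_fixed_durations_exact(self, tone_recording):
        ars = [AnnotatedEvent(1.0, 1.05, "crackle")]
        rge = generate_fixed_rge(tone_recording, ars, {0.050: 3, 0.150: 2}, seed=1)
        durs = sorted(round(e.duration, 6) for e in rge)
        assert durs == [0.05, 0.05, 0.05, 0.15, 0.15]
        assert {e.label for e in rge} == {"other50", "other150"}

    def test_fixed_deterministic_per_file(self, tone_recording):
        a = generate_fixed_rge(tone_recording, [], {0.050: 4}, seed=9)
        b = generate_fixed_rge(tone_recording, [], {0.050: 4}, seed=9)
        assert a == b

    def test_all_events_within_recording(self, tone_recording):
        rge = generate_fixed_rge(tone_recording, [], {0.050: 20, 0.150: 20}, seed=2)
        assert all(0 <= e.start and e.end <= tone_recording.duration for e in rge)

    def test_variable_truncations(self, tone_recording):
        rge = generate_variable_rge(tone_recording, [], 30, 10, seed=3)
        for e in rge:
            if e.label == "otherCrackle":
                assert e.duration <= 0.1
            else:
                assert e.label == "otherWheeze"
                assert 0.1 < e.duration <= 2.0

    def test_variable_zero_counts(self, tone_recording):
        assert generate_variable_rge(tone_recording, [], 0, 0, seed=0) == []

    def test_rge_avoid_annotated_events(self, tone_recording):
        ars = [AnnotatedEvent(i * 1.0, i * 1.0 + 0.8, "wheeze") for i in range(9)]
        rge = generate_fixed_rge(tone_recording, ars, {0.050: 10}, seed=4)
        for e in rge:
            for a in ars:
                assert e.end <= a.start or e.start >= a.end

    def test_pooled_variable_durations_pass_ks(self, tone_recording):
        """Pooled otherWheeze durations match the truncated model (alpha=0.01)."""
        durs = []
        for i in range(30):
            rec = tone_recording
            rec = type(rec)(rec.samples, rec.rate, "P1", f"R{i}")
            rge = generate_variable_rge(rec, [], 0, 10, seed=6)
            durs.extend(e.duration for e in rge)
        p = OTHER_WHEEZE_BURR
        lo, hi = float(burr_cdf(p.lower, p)), float(burr_cdf(p.upper, p))
        res = kstest(np.array(durs), lambda v: (burr_cdf(v, p) - lo) / (hi - lo))
        assert res.pvalue > 0.01


class TestExcerpt:
    def test_centered_zero_padding(self, tone_recording):
        ev = AnnotatedEvent(2.0, 3.0, "wheeze")  # 1.0 s at 4 kHz
        out = excerpt_event(tone_recording, ev)
        assert out.size == 8000
        assert np.all(out[:2000] == 0) and np.all(out[-2000:] == 0)
        assert np.any(out[2000:6000] != 0)

    def test_overlong_event_truncated_to_first_two_seconds(self, tone_recording):
        ev = AnnotatedEvent(1.0, 4.5, "wheeze")  # 3.5 s
        out = excerpt_event(tone_recording, ev)
        assert out.size == 8000
        assert np.allclose(out, tone_recording.samples[4000:12000])

    def test_exact_length_event_unchanged(self, tone_recording):
        ev = AnnotatedEvent(0.0, 2.0, "wheeze")
        out = excerpt_event(tone_recording, ev)
        assert np.array_equal(out, tone_recording.samples[:8000])

    def test_energy_conservation(self, tone_recording):
        """Zero padding adds no energy: output energy equals region energy."""
        ev = AnnotatedEvent(1.2345, 1.9, "crackle")
        out = excerpt_event(tone_recording, ev)
        i0, i1 = int(np.floor(1.2345 * 4000)), int(np.ceil(1.9 * 4000))
        assert np.isclose((out**2).sum(), (tone_recording.samples[i0:i1] ** 2).sum())

    def test_odd_pad_extra_sample_on_right(self, tone_recording):
        ev = AnnotatedEvent(0.0, 0.25025, "wheeze")  # 1001 samples
        out = excerpt_event(tone_recording, ev)
        n_seg = 1001
        left = (8000 - n_seg) // 2
        assert np.array_equal(out[left : left + n_seg], tone_recording.samples[:n_seg])
        assert np.all(out[:left] == 0)

    def test_event_outside_recording_rejected(self, tone_recording):
        with pytest.raises(ValidationError):
            excerpt_event(tone_recording, AnnotatedEvent(9.5, 10.7, "wheeze"))

    def test_invalid_policy(self):
        with pytest.raises(ValidationError):
            ExcerptPolicy(max_len=0.0)
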