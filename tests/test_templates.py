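"""Parametric template construction and synthetic subject groups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrsim import (
    CANONICAL_COMPONENTS,
    ComponentSpec,
    canonical_pair,
    generate_group,
    make_aep,
    make_component_wave,
    shift_component,
)

FS = 10_000.0
DUR = 100.0


def _local_extrema(wave, floor):
    """Indices of strict local extrema with |value| above floor."""
    out = []
    for i in range(1, wave.size - 1):
        if abs(wave[i]) <= floor:
            continue
        if wave[i] > wave[i - 1] and wave[i] > wave[i + 1]:
            out.append(i)
        elif wave[i] < wave[i - 1] and wave[i] < wave[i + 1]:
            out.append(i)
    return out


class TestComponentWave:
    def test_zero_amplitude_gives_zero_wave(self):
        spec = ComponentSpec("V", 6.0, 1.2, 0.0)
        assert np.all(make_component_wave(spec, FS, DUR) == 0)

    @pytest.mark.parametrize("kernel", ["gaussian", "spline"])
    def test_signed_peak_at_latency(self, kernel):
        spec = ComponentSpec("V", 6.0, 1.2, +1.0)
        wave = make_component_wave(spec, FS, DUR, kernel)
        assert wave[round(6.0 * FS / 1000.0)] == pytest.approx(1.0)
        assert np.argmax(wave) == round(6.0 * FS / 1000.0)

    def test_gaussian_area_matches_closed_form(self):
        # integral of A*exp(-(t-mu)^2/(2 w^2)) dt = A*w*sqrt(2 pi), t in ms
        spec = ComponentSpec("Pa", 50.0, 5.0, 0.7)
        wave = make_component_wave(spec, FS, DUR)
        area = wave.sum() / FS * 1000.0  # sample sum -> ms integral
        expected = 0.7 * 5.0 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(expected, rel=0.01)

    def test_component_outside_window_raises(self):
        with pytest.raises(ValueError, match="outside template window"):
            make_component_wave(ComponentSpec("Pb", 120.0, 5.0, 1.0), FS, DUR)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ComponentSpec("V", 6.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            ComponentSpec("", 6.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ComponentSpec("V", -2.0, 1.0, 1.0)


class TestMakeAep:
    def test_empty_component_list_gives_zero_template(self):
        t = make_aep([], FS, DUR)
        assert np.all(t.samples == 0)
        assert t.n_samples == 1000

    def test_construction_is_linear_in_components(self):
        a = CANONICAL_COMPONENTS[:2]
        b = CANONICAL_COMPONENTS[2:]
        whole = make_aep(CANONICAL_COMPONENTS, FS, DUR).samples
        parts = make_aep(a, FS, DUR).samples + make_aep(b, FS, DUR).samples
        np.testing.assert_allclose(whole, parts, atol=1e-15)

    def test_canonical_preset_has_five_extrema(self, canonical):
        # brute-force scan: exactly the V, Na, Pa, Nb, Pb peaks stand out
        found = _local_extrema(canonical.samples, floor=0.05)
        assert len(found) == 5
        signs = np.sign(canonical.samples[found])
        np.testing.assert_array_equal(signs, [1, -1, 1, -1, 1])

    def test_disjoint_bumps_peak_peak(self):
        comps = [
            ComponentSpec("a", 20.0, 1.0, +0.8),
            ComponentSpec("b", 70.0, 1.0, -0.5),
        ]
        t = make_aep(comps, FS, DUR)
        assert t.peak_peak() == pytest.approx(0.8 + 0.5, rel=1e-6)


class TestCanonicalPair:
    def test_v_to_pa_separation_is_25_ms(self):
        lat = {c.label: c.latency_ms for c in CANONICAL_COMPONENTS}
        assert lat["Pa"] - lat["V"] == 25.0

    def test_fig7_zero_delta_identical(self):
        a, b = canonical_pair("fig7", fig7_delta_ms=0.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_fig7_difference_restricted_to_pb_support(self):
        a, b = canonical_pair("fig7", fig7_delta_ms=8.0)
        pb = next(c for c in a.components if c.label == "Pb")
        cut = round((pb.latency_ms - 4 * pb.width_ms) * FS / 1000.0)
        assert np.max(np.abs(a.samples[:cut] - b.samples[:cut])) == 0
        assert np.max(np.abs(a.samples[cut:] - b.samples[cut:])) > 0

    def test_homo_zero_perturbation_identical(self):
        a, b = canonical_pair("homo", perturbation=0.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_homo_default_is_small_perturbation(self):
        a, b = canonical_pair("homo")
        rel = np.max(np.abs(a.samples - b.samples)) / a.peak_peak()
        assert 0 < rel < 0.1

    def test_hetero_alters_pa_nb_pb(self):
        a, b = canonical_pair("hetero")
        by = {c.label: c for c in b.components}
        ref = {c.label: c for c in a.components}
        assert by["Pa"].amplitude == pytest.approx(ref["Pa"].amplitude * 0.6)
        assert by["Nb"].amplitude == pytest.approx(ref["Nb"].amplitude * 1.3)
        assert by["Pb"].latency_ms == pytest.approx(ref["Pb"].latency_ms + 8.0)

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            canonical_pair("nope")


class TestShiftComponent:
    def test_zero_shift_is_identity(self, canonical):
        t = shift_component(canonical, "Pb", 0.0)
        np.testing.assert_array_equal(t.samples, canonical.samples)

    def test_pb_shift_moves_last_positive_extremum(self):
        # disjoint bumps, so the peak location is exactly the latency sample
        comps = [
            ComponentSpec("Pa", 30.0, 2.0, +0.5),
            ComponentSpec("Pb", 55.0, 2.0, +0.45),
        ]
        t = make_aep(comps, FS, DUR)
        shifted = shift_component(t, "Pb", 8.0)
        last_before = _local_extrema(t.samples, 0.05)[-1]
        last_after = _local_extrema(shifted.samples, 0.05)[-1]
        assert last_after - last_before == round(8.0 * FS / 1000.0)

    def test_pb_shift_on_canonical_moves_peak_approximately(self, canonical):
        # overlapping neighbours perturb the exact argmax by a sample or two
        shifted = shift_component(canonical, "Pb", 8.0)
        last_before = _local_extrema(canonical.samples, 0.05)[-1]
        last_after = _local_extrema(shifted.samples, 0.05)[-1]
        assert abs((last_after - last_before) - 80) <= 5

    def test_shift_past_window_raises(self, canonical):
        with pytest.raises(ValueError, match="outside template window"):
            shift_component(canonical, "Pb", 50.0)

    def test_nonparametric_template_raises(self, canonical):
        from ssrsim import AepTemplate

        bare = AepTemplate(canonical.samples.copy(), FS, DUR)
        with pytest.raises(ValueError, match="not a parametric template"):
            shift_component(bare, "Pb", 1.0)
        with pytest.raises(ValueError, match="not a parametric template"):
            shift_component(canonical, "Qz", 1.0)


class TestGenerateGroup:
    def test_zero_variability_reproduces_mean(self, canonical):
        g = generate_group(canonical, 4, 0.0, 0.0, 0.0, seed=7)
        for wave in g.waves:
            np.testing.assert_array_equal(wave, canonical.samples)

    def test_same_seed_is_bit_reproducible(self, canonical):
        g1 = generate_group(canonical, 5, 0.1, 1.0, 0.05, seed=3)
        g2 = generate_group(canonical, 5, 0.1, 1.0, 0.05, seed=3)
        np.testing.assert_array_equal(g1.waves, g2.waves)

    def test_growing_group_keeps_existing_subjects(self, canonical):
        small = generate_group(canonical, 5, 0.1, 1.0, 0.05, seed=3)
        big = generate_group(canonical, 8, 0.1, 1.0, 0.05, seed=3)
        np.testing.assert_array_equal(big.waves[:5], small.waves)

    def test_noise_sd_calibration(self, canonical):
        g = generate_group(canonical, 200, 0.0, 0.0, 0.04, seed=11)
        sd = g.waves.std(axis=0, ddof=1).mean()
        assert sd == pytest.approx(0.04, rel=0.2)

    def test_variability_needs_parametric_template(self, canonical):
        from ssrsim import AepTemplate

        bare = AepTemplate(canonical.samples.copy(), FS, DUR)
        with pytest.raises(ValueError, match="parametric"):
            generate_group(bare, 5, amp_cv=0.1, seed=0)
        # noise-only groups work on bare sample templates
        g = generate_group(bare, 3, 0.0, 0.0, 0.01, seed=0)
        assert g.n_subjects == 3

    def test_too_few_subjects_raises(self, canonical):
        with pytest.raises(ValueError, match="at least 2"):
            generate_group(canonical, 1, seed=0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    amp=st.floats(-2, 2, allow_nan=False),
    lat=st.floats(5, 90),
    width=st.floats(0.5, 8),
)
def test_component_wave_bounded_by_amplitude(amp, lat, width):
    wave = make_component_wave(ComponentSpec("x", lat, width, amp), FS, DUR)
    assert np.max(np.abs(wave)) <= abs(amp) + 1e-12
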