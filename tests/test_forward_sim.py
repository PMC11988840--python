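import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from lamdiff import (
    GaussianComponent,
    InputError,
    InstrumentConfig,
    MembraneProfileSpec,
    PRESET_LABELS,
    SampleCondition,
    build_profile,
    fixture_preset,
    intensities_from_factors,
    structure_factor_amplitudes,
    structure_factors_from_profile,
    synth_diffractogram,
    synth_omega_map,
    theta_from_q,
    trough_depth,
    synthesize_profile,
)
from lamdiff.nsld import StructureFactorSet
from lamdiff.reduction import integrate_roi


class TestBuildProfile:
    def test_zero_components_gives_zero_profile(self):
        spec = MembraneProfileSpec(period_d=50.0, components=[], n_orders=3)
        prof = build_profile(spec, 128)
        assert np.all(prof.rho == 0)

    def test_headgroup_pair_has_two_equal_maxima(self):
        spec = MembraneProfileSpec(
            period_d=50.0,
            components=[GaussianComponent("headgroup", 20.0, 2.0, 1.0)],
            n_orders=3,
        )
        prof = build_profile(spec, 1000)
        i_pos = np.argmax(prof.rho[prof.z_grid > 0])
        i_neg = np.argmax(prof.rho[prof.z_grid < 0])
        z_pos = prof.z_grid[prof.z_grid > 0][i_pos]
        z_neg = prof.z_grid[prof.z_grid < 0][i_neg]
        assert z_pos == pytest.approx(20.0, abs=prof.dz)
        assert z_neg == pytest.approx(-20.0, abs=prof.dz)
        assert prof.rho[prof.z_grid > 0][i_pos] == pytest.approx(
            prof.rho[prof.z_grid < 0][i_neg], rel=1e-9
        )

    def test_diether_preset_has_midplane_trough(self):
        spec = fixture_preset("D", SampleCondition(60.0, 95.0, 0.08))
        prof = build_profile(spec, 512)
        i0 = prof.z_grid.size // 2
        assert prof.rho[i0] < prof.rho[i0 - 4]
        assert prof.rho[i0] < prof.rho[i0 + 4]

    def test_component_beyond_half_period_rejected(self):
        with pytest.raises(InputError, match="headgroup"):
            MembraneProfileSpec(
                period_d=50.0,
                components=[GaussianComponent("headgroup", 26.0, 2.0, 1.0)],
                n_orders=3,
            )

    @given(
        center=st.floats(0.0, 20.0),
        sigma=st.floats(0.5, 6.0),
        amp=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_profiles_are_even(self, center, sigma, amp):
        spec = MembraneProfileSpec(
            period_d=50.0,
            components=[GaussianComponent("CH2", center, sigma, amp)],
            n_orders=4,
        )
        rho = build_profile(spec, 256).rho
        assert np.max(np.abs(rho[1:] - rho[1:][::-1])) <= 1e-9 * max(
            np.max(np.abs(rho)), 1e-30
        )


class TestStructureFactorsFromProfile:
    def test_constant_profile_has_zero_moments(self):
        spec = MembraneProfileSpec(period_d=50.0, components=[], n_orders=4)
        prof = build_profile(spec, 256)
        prof.rho = prof.rho + 3.7
        sf = structure_factors_from_profile(prof, 4)
        assert np.allclose(sf.amplitudes, 0.0, atol=1e-12)

    def test_pure_cosine_first_order(self):
        d = 50.0
        spec = MembraneProfileSpec(period_d=d, components=[], n_orders=4)
        prof = build_profile(spec, 256)
        prof.rho = np.cos(2 * np.pi * prof.z_grid / d)
        sf = structure_factors_from_profile(prof, 3)
        assert sf.signs[0] * sf.amplitudes[0] == pytest.approx(d / 2, rel=1e-12)
        assert np.allclose(sf.amplitudes[1:], 0.0, atol=1e-12)

    def test_matches_adaptive_quadrature_oracle(self):
        spec = fixture_preset("D", SampleCondition(60.0, 95.0, 0.08))
        prof = build_profile(spec, 512)
        sf = structure_factors_from_profile(prof, spec.n_orders)
        d = spec.period_d

        def rho_fn(z):
            out = 0.0
            for c in spec.components:
                centers = (c.center_z, -c.center_z) if c.center_z > 0 else (0.0,)
                for cc in centers:
                    for k in range(-3, 4):
                        out += c.amplitude * np.exp(
                            -0.5 * ((z - cc - k * d) / c.width_sigma) ** 2
                        )
            return out

        for h, amp, sign in zip(sf.orders, sf.amplitudes, sf.signs):
            oracle, _ = quad(
                lambda z: rho_fn(z) * np.cos(2 * np.pi * h * z / d),
                -d / 2, d / 2, limit=200,
            )
            assert sign * amp == pytest.approx(oracle, rel=1e-6)

    def test_rejects_odd_profile(self):
        spec = MembraneProfileSpec(period_d=50.0, components=[], n_orders=3)
        prof = build_profile(spec, 256)
        prof.rho = np.sin(2 * np.pi * prof.z_grid / 50.0)
        with pytest.raises(InputError, match="odd"):
            structure_factors_from_profile(prof, 3)


class TestIntensitiesFromFactors:
    def test_zero_amplitude_gives_zero_intensity(self, instrument):
        sf = StructureFactorSet(50.0, [1, 2], np.array([0.0, 2.0]))
        tts = theta_from_q(2 * np.pi * np.array([1, 2]) / 50.0)
        intensities = intensities_from_factors(sf, instrument, tts)
        assert intensities[0] == 0.0

    def test_identity_limit_no_corrections(self):
        # mu_t = 0, 2theta = 90 deg, beam much narrower than footprint
        inst = InstrumentConfig(mu_t=0.0, sample_length_L=1e4,
                                beam_half_width_delta=1e-3)
        sf = StructureFactorSet(50.0, [1], np.array([3.0]))
        intensities = intensities_from_factors(sf, inst, [90.0])
        assert intensities[0] == pytest.approx(9.0, rel=1e-12)

    def test_round_trip_through_amplitudes(self, instrument, ctx, render):
        spec, sf, diff = render("T", 70, 95)
        tts = np.asarray(diff.metadata["peak_two_thetas"])
        intensities = intensities_from_factors(sf, instrument, tts)
        from lamdiff.reduction import BraggPeak, BraggPeakSet

        peaks = BraggPeakSet(
            peaks=[
                BraggPeak(h, tt, 0.0, I, 0.0, 0.25)
                for h, tt, I in zip(sf.orders, tts, intensities)
            ]
        )
        back = structure_factor_amplitudes(peaks, ctx, sf.d_spacing)
        assert np.allclose(back.amplitudes, sf.amplitudes, rtol=1e-9)
        intensities2 = intensities_from_factors(back, instrument, tts)
        assert np.allclose(intensities2, intensities, rtol=1e-9)


class TestSynthDiffractogram:
    def test_total_signal_matches_quadrature_oracle(self, render):
        spec, sf, diff = render("DT11", 70, 95, noise="none")
        inst = InstrumentConfig()
        total = np.sum(diff.counts) * inst.two_theta_step
        expected = sum(diff.metadata["true_intensities"]) * inst.counts_scale
        assert total == pytest.approx(expected, rel=1e-6)

    def test_zero_amplitudes_give_flat_background(self):
        inst = InstrumentConfig(background_slope=1.0, background_intercept=100.0)
        sf = StructureFactorSet(50.0, [1, 2], np.zeros(2))
        diff = synth_diffractogram(sf, inst, noise="none")
        tt = diff.two_theta_deg
        assert np.allclose(diff.counts, 1.0 * tt + 100.0)

    def test_poisson_counts_nonnegative_and_seeded(self, render):
        _, _, d1 = render("D", 60, 95, noise="poisson", seed=7)
        _, _, d2 = render("D", 60, 95, noise="poisson", seed=7)
        _, _, d3 = render("D", 60, 95, noise="poisson", seed=8)
        assert np.all(d1.counts >= 0)
        assert np.array_equal(d1.counts, d2.counts)
        assert not np.array_equal(d1.counts, d3.counts)

    def test_rerendered_preset_order_count_detected(self, render):
        from lamdiff.reduction import detect_peaks

        spec, _, diff = render("DT11", 70, 95, noise="none")
        assert len(detect_peaks(diff)) == spec.n_orders == 4

    def test_overlapping_orders_warn_in_metadata(self):
        inst = InstrumentConfig(peak_width_2theta=3.0)
        sf = StructureFactorSet(50.0, [1, 2], np.array([1.0, 1.0]))
        with pytest.warns(UserWarning, match="overlap"):
            diff = synth_diffractogram(sf, inst, noise="none")
        assert "overlapping_orders" in diff.metadata["warnings"]


class TestSynthOmegaMap:
    def test_map_dimensions_match_scan_protocol(self, render):
        # Omega from -1 to 13 deg in 0.05-deg steps
        _, sf, _ = render("T", 70, 95)
        rmap = synth_omega_map(sf, InstrumentConfig(), mosaic_sigma=0.5)
        assert rmap.omega_deg.size == 281
        assert rmap.omega_deg[0] == pytest.approx(-1.0)
        assert rmap.omega_deg[-1] == pytest.approx(13.0)
        assert np.allclose(np.diff(rmap.omega_deg), 0.05)

    def test_roi_integration_recovers_diffractogram(self, render):
        _, sf, diff = render("DT21", 70, 95, noise="none")
        rmap = synth_omega_map(sf, InstrumentConfig(), mosaic_sigma=0.4)
        reduced = integrate_roi(rmap)
        scale = np.max(diff.counts)
        assert np.allclose(reduced.counts / scale, diff.counts / scale, atol=1e-6)

    def test_small_mosaic_concentrates_on_specular_rows(self, render):
        _, sf, _ = render("T", 70, 95)
        inst = InstrumentConfig()
        rmap = synth_omega_map(sf, inst, mosaic_sigma=0.02)
        for tt in rmap.metadata["peak_two_thetas"]:
            j = np.argmin(np.abs(rmap.two_theta_deg - tt))
            col = rmap.intensity[:, j]
            i = np.argmax(col)
            assert rmap.omega_deg[i] == pytest.approx(tt / 2, abs=0.05)
            window = np.abs(rmap.omega_deg - tt / 2) < 0.1
            assert col[window].sum() > 0.99 * col.sum()


class TestFixturePreset:
    def test_unknown_label_rejected(self):
        with pytest.raises(InputError, match="unknown preset"):
            fixture_preset("X", SampleCondition())

    def test_headgroup_amplitude_ratio_T_to_D(self):
        t = fixture_preset("T", SampleCondition(70, 95, 0.08))
        d = fixture_preset("D", SampleCondition(70, 95, 0.08))
        amp_t = [c for c in t.components if c.moiety == "headgroup"][0].amplitude
        amp_d = [c for c in d.components if c.moiety == "headgroup"][0].amplitude
        assert amp_t == pytest.approx(1.0)
        assert amp_d == pytest.approx(0.2)

    def test_trough_deeper_in_DT21_than_DT11(self):
        depths = {}
        for label in ("DT11", "DT21"):
            spec = fixture_preset(label, SampleCondition(70, 95, 0.08))
            sf = structure_factors_from_profile(build_profile(spec, 512), spec.n_orders)
            depths[label] = trough_depth(synthesize_profile(sf, 512))
        assert depths["DT21"] > depths["DT11"]

    @pytest.mark.parametrize("label", PRESET_LABELS)
    def test_water_component_vanishes_at_null_contrast(self, label):
        spec = fixture_preset(label, SampleCondition(70, 95, 0.08))
        water = [c for c in spec.components if c.moiety == "water"]
        assert not water  # amplitude would be exactly 0; component omitted

    @pytest.mark.parametrize("label", PRESET_LABELS)
    def test_water_component_present_at_full_contrast(self, label):
        spec = fixture_preset(label, SampleCondition(70, 95, 1.0))
        water = [c for c in spec.components if c.moiety == "water"]
        assert len(water) == 1 and water[0].amplitude > 0

    def test_ch3_negative_at_null_contrast(self):
        for label in ("D", "DT11", "DT21"):
            spec = fixture_preset(label, SampleCondition(70, 95, 0.08))
            ch3 = [c for c in spec.components if c.moiety == "CH3"]
            assert ch3 and ch3[0].amplitude < 0

    def test_spec_round_trips_through_yaml(self, tmp_path):
        from lamdiff.io import read_profile_spec, write_profile_spec

        spec = fixture_preset("DT11", SampleCondition(70, 95, 0.08))
        path = tmp_path / "spec.yaml"
        write_profile_spec(spec, path)
        back = read_profile_spec(path)
        assert back.period_d == spec.period_d
        assert back.n_orders == spec.n_orders
        assert len(back.components) == len(spec.components)
        for a, b in zip(back.components, spec.components):
            assert (a.moiety, a.center_z, a.width_sigma, a.amplitude) == (
                b.moiety, b.center_z, b.width_sigma, b.amplitude,
            )


class TestEndToEndRecovery:
    @pytest.mark.parametrize("label", PRESET_LABELS)
    def test_noise_free_recovery(self, label, ctx, render):
        from lamdiff.profile_metrics import analyze_diffractogram

        spec, sf, diff = render(label, 70, 95, noise="none")
        m = analyze_diffractogram(diff, ctx, spec.condition, label=label)
        assert abs(m.d_spacing - spec.period_d) < 0.1
        if spec.n_orders >= 3:
            truth = tuple(int(s) for s in sf.signs)
            neg = tuple(-s for s in truth)
            assert m.signs in (truth, neg)
            assert abs(m.d_b - spec.d_b_nominal) < 0.5

    def test_noisy_d_within_3_sigma_coverage(self, ctx, render):
        """>= 99% of replicates within 3 sigma_d at counts_scale 1e4."""
        from lamdiff.lamellar import dspacing_linear
        from lamdiff.reduction import detect_peaks, fit_peaks

        n_rep, hits = 500, 0
        for seed in range(n_rep):
            _, _, diff = render(
                "DT11", 70, 95, noise="poisson", seed=seed, counts_scale=1e4
            )
            cands = detect_peaks(diff)
            peaks = fit_peaks(diff, cands)
            fit = dspacing_linear(peaks)
            if abs(fit.d_spacing - 55.3) <= 3 * fit.sigma_d:
                hits += 1
        assert hits / n_rep >= 0.99
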