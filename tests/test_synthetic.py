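"""Generator determinism, closure against the analysis pipeline, noise scaling."""

import math

import numpy as np
import pytest

import gelmech as g
from gelmech.pipeline import analyze_ring_record

from conftest import RING_FAILURE, make_material


def ring_spec(material, geom, **kwargs):
    return g.GeneratorSpec(material=material, geometry=geom, **kwargs)


class TestRingTensileGenerator:
    def test_deterministic_and_seed_independent_when_noiseless(self, ring_geometry):
        mat = make_material("0.5:0.5", d1=0.05)
        rec1 = g.generate_ring_tensile_record(ring_spec(mat, ring_geometry, seed=1))
        rec2 = g.generate_ring_tensile_record(ring_spec(mat, ring_geometry, seed=99))
        np.testing.assert_array_equal(rec1.force, rec2.force)
        np.testing.assert_array_equal(rec1.displacement, rec2.displacement)

    def test_record_structure(self, ring_geometry):
        mat = make_material("0.5:0.5", d1=0.05)
        spec = ring_spec(mat, ring_geometry)
        rec = g.generate_ring_tensile_record(spec)
        assert rec.time[0] == 0.0 and rec.displacement[0] == 0.0
        assert rec.force[0] == 0.0
        assert np.all(np.diff(rec.force) > 0)  # noiseless: strictly increasing
        np.testing.assert_allclose(
            np.diff(rec.displacement), spec.crosshead_speed / spec.sample_rate
        )

    def test_failure_strain_matches_closed_form_damage_integral(self, ring_geometry):
        # constant fracture strain: damage hits 1 exactly at eps_p = d1,
        # so the last-sample ring strain solves
        # ln(1 + eps_r) = d1 + sigma_flow(d1) / E  (monotonic loading)
        mat = make_material("1:0", d1=0.002)
        spec = ring_spec(mat, ring_geometry)
        rec = g.generate_ring_tensile_record(spec)
        rate = g.nominal_ring_strain_rate(spec)
        eps_true_fail = 0.002 + g.jc_stress(mat, 0.002, rate) / mat.youngs_modulus
        expected_ring_strain = math.expm1(eps_true_fail)
        last_ring_strain = 2 * rec.displacement[-1] / ring_geometry.initial_circumference
        step = 2 * spec.crosshead_speed / spec.sample_rate / (
            ring_geometry.initial_circumference
        )
        assert abs(last_ring_strain - expected_ring_strain) <= step

    def test_noise_statistics(self, ring_geometry):
        mat = make_material("0.5:0.5", d1=0.25)  # long record for statistics
        clean = g.generate_ring_tensile_record(
            ring_spec(mat, ring_geometry, sample_rate=500.0)
        )
        noisy = g.generate_ring_tensile_record(
            ring_spec(mat, ring_geometry, sample_rate=500.0, noise_sd=0.01, seed=5)
        )
        resid = noisy.force[1:] - clean.force[1:]
        target = 0.01 * clean.force.max()
        assert abs(resid.mean()) < 0.2 * target  # zero-mean
        assert abs(resid.std() - target) < 0.2 * target

    def test_noise_scaling_is_linear(self, ring_geometry):
        mat = make_material("0.5:0.5", d1=0.25)
        kw = dict(sample_rate=500.0, seed=11)
        clean = g.generate_ring_tensile_record(ring_spec(mat, ring_geometry, **kw))
        lo = g.generate_ring_tensile_record(
            ring_spec(mat, ring_geometry, noise_sd=0.01, **kw)
        )
        hi = g.generate_ring_tensile_record(
            ring_spec(mat, ring_geometry, noise_sd=0.02, **kw)
        )
        sd_lo = (lo.force - clean.force).std()
        sd_hi = (hi.force - clean.force).std()
        assert sd_hi == pytest.approx(2 * sd_lo, rel=1e-6)

    def test_infinite_fracture_strain_rejected(self, ring_geometry):
        mat = make_material("0.5:0.5")  # all damage constants zero
        with pytest.raises(ValueError, match="d1"):
            g.generate_ring_tensile_record(ring_spec(mat, ring_geometry))

    @pytest.mark.parametrize("ratio", list(RING_FAILURE))
    def test_round_trip_closure(self, ratio, ring_geometry):
        """Noiseless record pushed through the mechanics pipeline returns
        the configured failure point within 2%."""
        stress_target, strain_target = RING_FAILURE[ratio]
        spec0 = g.GeneratorSpec(
            material=make_material("1:0", d1=1.0), geometry=ring_geometry
        )
        rate = g.nominal_ring_strain_rate(spec0)
        mat = g.calibrate_ring_material(stress_target, strain_target, rate)
        rec = g.generate_ring_tensile_record(ring_spec(mat, ring_geometry))
        result = analyze_ring_record(rec, ring_geometry)
        assert result["failure"].stress == pytest.approx(stress_target, rel=0.02)
        assert result["failure"].strain == pytest.approx(strain_target, rel=0.02)

    def test_modulus_recovered_from_generated_record(self, ring_geometry):
        """The linear-region fit on a noiseless record returns the
        configured Young's modulus within 1%."""
        mat = make_material("0.5:0.5", d1=0.05)
        rec = g.generate_ring_tensile_record(ring_spec(mat, ring_geometry))
        result = analyze_ring_record(rec, ring_geometry)
        true = result["true_curve"]
        # select a fraction safely inside the elastic range
        modulus = g.youngs_modulus(true, linear_fraction=0.15)
        assert modulus == pytest.approx(8388e3, rel=0.01)


class TestCompressionGenerator:
    def make_spec(self, geom, law, **kwargs):
        mat = g.JohnsonCookMaterial(youngs_modulus=1.0, yield_strength=1.0)
        return g.GeneratorSpec(
            material=mat, geometry=geom, compression_law=law, **kwargs
        )

    def test_failure_detected_at_configuration(self, compression_geometry):
        law = g.CompressionLaw(peak_stress=0.69e6, failure_strain=0.33)
        rec = g.generate_compression_record(self.make_spec(compression_geometry, law))
        curve = g.compression_curve(rec, compression_geometry)
        fp = g.detect_failure(curve)
        step = curve.strain[1] - curve.strain[0]
        assert abs(fp.strain - 0.33) <= step
        assert fp.stress == pytest.approx(0.69e6, rel=0.01)

    def test_strain_spans_to_eighty_percent(self, compression_geometry):
        law = g.CompressionLaw(peak_stress=0.5e6, failure_strain=0.3)
        rec = g.generate_compression_record(self.make_spec(compression_geometry, law))
        curve = g.compression_curve(rec, compression_geometry)
        assert curve.strain[0] == 0.0
        assert curve.strain[-1] == pytest.approx(0.8, abs=1e-3)

    def test_convex_before_failure(self, compression_geometry):
        law = g.CompressionLaw(peak_stress=0.69e6, failure_strain=0.33)
        rec = g.generate_compression_record(self.make_spec(compression_geometry, law))
        curve = g.compression_curve(rec, compression_geometry)
        pre = curve.stress[curve.strain <= 0.33]
        assert np.all(np.diff(pre, 2) >= -1e-9)

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError, match="peak_stress"):
            g.CompressionLaw(peak_stress=0.0, failure_strain=0.33)

    @pytest.mark.parametrize("bad_strain", [0.0, 0.8, 0.95])
    def test_failure_strain_out_of_range_rejected(self, bad_strain):
        with pytest.raises(ValueError, match="failure strain"):
            g.CompressionLaw(peak_stress=0.5e6, failure_strain=bad_strain)


class TestWaveformGenerator:
    def test_sample_count_and_pure_strain_sinusoid(self):
        spec = g.WaveformSpec(
            storage_modulus=10e3, loss_modulus=1e3, n_cycles=5, samples_per_cycle=64
        )
        wave = g.generate_laos_waveform(spec)
        assert wave.time.size == 5 * 64
        t = wave.time
        expected = spec.strain_amplitude * np.sin(wave.angular_frequency * t)
        np.testing.assert_allclose(wave.strain, expected, atol=1e-15)

    def test_fixed_seed_reproducibility(self):
        spec = g.WaveformSpec(
            storage_modulus=10e3, loss_modulus=1e3, noise_sd=50.0, seed=7
        )
        w1 = g.generate_laos_waveform(spec)
        w2 = g.generate_laos_waveform(spec)
        np.testing.assert_array_equal(w1.stress, w2.stress)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            g.WaveformSpec(storage_modulus=1.0, loss_modulus=1.0, samples_per_cycle=8)


class TestSpeckleGenerator:
    def test_identity_pair_is_bitwise_equal(self):
        pair = g.generate_speckle_pair(g.SpeckleSpec(seed=2))
        np.testing.assert_array_equal(pair.reference, pair.deformed)

    def test_translation_truth_is_constant(self):
        deform = g.AffineDeformation(translation=(3.0, -2.0))
        pair = g.generate_speckle_pair(g.SpeckleSpec(deformation=deform, seed=2))
        u, v = pair.displacement_truth(np.array([10.0, 100.0]), np.array([20.0, 50.0]))
        np.testing.assert_allclose(u, 3.0)
        np.testing.assert_allclose(v, -2.0)

    def test_uniform_stretch_truth(self):
        deform = g.AffineDeformation(gradient=((1.01, 0.0), (0.0, 1.0)))
        pair = g.generate_speckle_pair(g.SpeckleSpec(deformation=deform, seed=2))
        x = np.linspace(10, 200, 5)
        u, v = pair.displacement_truth(x, np.full(5, 30.0))
        np.testing.assert_allclose(u / x, 0.01, rtol=1e-12)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_out_of_frame_deformation_rejected(self):
        deform = g.AffineDeformation(translation=(300.0, 0.0))
        with pytest.raises(ValueError, match="out of frame"):
            g.generate_speckle_pair(g.SpeckleSpec(deformation=deform, seed=2))

    def test_determinism(self):
        spec = g.SpeckleSpec(
            deformation=g.AffineDeformation(translation=(1.5, 0.5)),
            intensity_noise_sd=2.0,
            seed=4,
        )
        p1 = g.generate_speckle_pair(spec)
        p2 = g.generate_speckle_pair(spec)
        np.testing.assert_array_equal(p1.reference, p2.reference)
        np.testing.assert_array_equal(p1.deformed, p2.deformed)
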