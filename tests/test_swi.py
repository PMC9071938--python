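import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pddc.swi import (
    MagnitudePhasePair,
    PhaseMask,
    SWIVolume,
    compose_swi,
    highpass_phase,
    min_intensity_projection,
    negative_phase_mask,
    swi_from_complex,
)


def _pair(mag, phase):
    return MagnitudePhasePair(mag, phase, (1.0, 1.0, 1.0))


class TestHighpassPhase:
    def test_constant_phase_removed(self):
        mag = np.ones((64, 64, 4))
        phase = np.full((64, 64, 4), 0.7)
        corrected = highpass_phase(_pair(mag, phase), window=32)
        assert np.abs(corrected).max() < 1e-6

    def test_slow_ramp_strongly_suppressed(self):
        """A linear phase ramp varying over scales much larger than the
        filter window is background and must shrink by >= 10x."""
        n = 128
        x = np.linspace(-0.5, 0.5, n)
        phase = np.tile(0.6 * x[:, None], (1, n))[..., None]
        mag = np.ones((n, n, 1))
        corrected = highpass_phase(_pair(mag, phase), window=64)
        interior = corrected[16:-16, 16:-16, 0]
        assert np.abs(interior).max() <= np.abs(phase).max() / 10

    def test_point_defect_preserved(self):
        """A focal phase dip on flat background is high-frequency content:
        it must survive with the same sign and at least half its depth."""
        n = 96
        phase = np.zeros((n, n, 1))
        phase[46:50, 46:50, 0] = -1.0
        mag = np.ones((n, n, 1))
        corrected = highpass_phase(_pair(mag, phase), window=32)
        assert corrected[47, 47, 0] < -0.5

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            highpass_phase(_pair(np.ones((16, 16, 2)), np.zeros((16, 16, 2))), window=64)

    def test_nonstandard_window_warns(self):
        pair = _pair(np.ones((64, 64, 2)), np.zeros((64, 64, 2)))
        with pytest.warns(UserWarning):
            highpass_phase(pair, window=48)


class TestNegativePhaseMask:
    @pytest.mark.parametrize(
        "phi,m,expected",
        [(0.0, 4, 1.0), (-np.pi, 4, 0.0), (-np.pi / 2, 4, 0.0625), (0.5, 4, 1.0),
         (-np.pi / 2, 1, 0.5)],
    )
    def test_stated_values(self, phi, m, expected):
        mask = negative_phase_mask(np.array([[phi]]), m=m)
        assert np.isclose(mask.weights[0, 0], expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-np.pi, max_value=np.pi), st.integers(0, 8))
    def test_weights_always_in_unit_interval(self, phi, m):
        mask = negative_phase_mask(np.array([phi]), m=m)
        assert 0.0 <= mask.weights[0] <= 1.0


class TestComposeSWI:
    def test_neutral_mask_is_identity(self, rng):
        mag = np.abs(rng.normal(size=(8, 8, 4)))
        pair = _pair(mag, np.zeros_like(mag))
        swi = compose_swi(pair, negative_phase_mask(np.zeros_like(mag), m=0))
        assert np.array_equal(swi.values, mag)

    def test_zero_mask_annihilates(self, rng):
        mag = np.abs(rng.normal(size=(8, 8, 4)))
        pair = _pair(mag, np.zeros_like(mag))
        swi = compose_swi(pair, PhaseMask(np.zeros_like(mag), 4))
        assert not swi.values.any()

    def test_swi_never_exceeds_magnitude(self, small_subject):
        swi = swi_from_complex(small_subject.complex_image, window=32)
        assert np.all(swi.values <= small_subject.complex_image.magnitude + 1e-12)

    def test_shape_mismatch_rejected(self):
        pair = _pair(np.ones((4, 4, 2)), np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            compose_swi(pair, PhaseMask(np.ones((3, 3, 2)), 4))

    def test_cmb_darkened_relative_to_magnitude(self, small_subject):
        """Implanted microbleed voxels carry negative phase, so the mask must
        attenuate them: mean SWI < mean MI inside the lesion."""
        swi = swi_from_complex(small_subject.complex_image, window=32)
        mag = small_subject.complex_image.magnitude
        cls, center, diameter = [l for l in small_subject.truth_lesions if l[0] == "cmb"][0]
        sp = np.array(small_subject.spacing)
        idx = np.indices(mag.shape).transpose(1, 2, 3, 0) * sp
        inside = np.linalg.norm(idx - np.array(center), axis=-1) <= diameter / 2
        assert swi.values[inside].mean() < 0.8 * mag[inside].mean()

    def test_veins_more_conspicuous_on_swi(self):
        """A vein with weak magnitude contrast but susceptibility phase is
        scarcely visible on MI yet dark on SWI: the fraction of vein voxels
        below 60% of the tissue level must rise after phase weighting."""
        from pddc.phantom import PhantomSpec, make_phantom

        a, b = np.array([30.0, 80.0, 30.0]), np.array([90.0, 80.0, 34.0])
        spec = PhantomSpec(
            grid_shape=(64, 64, 32),
            voxel_spacing=(2.0, 2.0, 2.0),
            vein_specs=[([tuple(a), tuple(b)], 2.0, 0.2)],
            noise_sigma=0.005,
            seed=21,
        )
        subject = make_phantom(spec)
        swi = swi_from_complex(subject.complex_image, window=32)
        mag = subject.complex_image.magnitude
        sp = np.array(subject.spacing)
        idx = np.indices(mag.shape).transpose(1, 2, 3, 0) * sp
        ab = b - a
        t = np.clip(((idx - a) @ ab) / (ab @ ab), 0, 1)
        dist = np.linalg.norm(idx - (a + t[..., None] * ab), axis=-1)
        vein = dist <= 2.0
        tissue = mag > 0.3 * mag.max()
        bg_mag = np.median(mag[tissue])
        bg_swi = np.median(swi.values[tissue])
        frac_mag = np.mean(mag[vein] < 0.6 * bg_mag)
        frac_swi = np.mean(swi.values[vein] < 0.6 * bg_swi)
        assert frac_swi > frac_mag


class TestMinIntensityProjection:
    def test_single_slice_slab_is_identity(self, rng):
        vol = SWIVolume(np.abs(rng.normal(size=(6, 6, 5))))
        out = min_intensity_projection(vol, 1)
        assert np.array_equal(out, vol.values)

    def test_two_slice_slab_is_elementwise_min(self, rng):
        vals = np.abs(rng.normal(size=(6, 6, 2)))
        out = min_intensity_projection(SWIVolume(vals), 2)
        assert np.array_equal(out[:, :, 0], np.minimum(vals[:, :, 0], vals[:, :, 1]))

    def test_full_depth_projection_bounded_by_every_slice(self, rng):
        vals = np.abs(rng.normal(size=(6, 6, 7)))
        out = min_intensity_projection(SWIVolume(vals), 7)
        for k in range(7):
            assert np.all(out[:, :, 0] <= vals[:, :, k])

    def test_full_depth_idempotent(self, rng):
        vals = np.abs(rng.normal(size=(6, 6, 7)))
        once = min_intensity_projection(SWIVolume(vals), 7)
        twice = min_intensity_projection(SWIVolume(once), once.shape[2])
        assert np.array_equal(once, twice)

    def test_overthick_slab_clamped_with_warning(self, rng):
        vals = np.abs(rng.normal(size=(4, 4, 3)))
        with pytest.warns(UserWarning):
            out = min_intensity_projection(SWIVolume(vals), 10)
        assert out.shape == (4, 4, 1)
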