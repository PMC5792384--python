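"""Demons registration, warping, attenuation transport and study assembly."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift

from petmoco import (DemonsSettings, LABELS, MotionField, MotionPhaseSpec,
                     assemble_study, demons_register, estimate_all_fields,
                     true_deformation, warp_attenuation_map, warp_image)
from petmoco.mr import simulate_all_phases
from petmoco.motion import invert_field
from petmoco.phantom import warp_map


@pytest.fixture(scope="module")
def blob():
    img = np.zeros((64, 64))
    img[24:40, 26:42] = 1.0
    return gaussian_filter(img, 3.0)


@pytest.fixture(scope="module")
def crm_small_spec():
    return MotionPhaseSpec.crm(n_cardiac=2, n_resp=2, cardiac_amplitude=0.10,
                               resp_amplitude=10.0)


@pytest.fixture(scope="module")
def mr_and_fields(phantom, crm_small_spec):
    images = simulate_all_phases(phantom, crm_small_spec)
    fields = estimate_all_fields(images, crm_small_spec.reference_phase,
                                 phantom.pixel_size)
    return images, fields


class TestDemonsRegister:
    def test_identity_registration(self, blob):
        f = demons_register(blob, blob, 1.0)
        assert f.magnitude().max() < 0.05

    def test_known_shift_recovery(self, blob):
        moving = nd_shift(blob, (0.0, 2.0))  # content moved +2 columns
        f = demons_register(blob, moving, 1.0)
        core = blob > 0.5 * blob.max()
        # pull-back: sampling moving at x+u must land on the fixed content
        assert abs(f.displacement[1][core].mean() - 2.0) < 0.3
        assert abs(f.displacement[0][core].mean()) < 0.3
        warped = warp_image(moving, f)
        assert np.abs(warped - blob)[core].max() < 0.1 * blob.max()

    def test_radial_contraction_similarity(self, blob):
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        u = np.stack([(rr - 32) * 0.05, (cc - 32) * 0.05])
        moving = warp_map(blob, u, 1.0)
        f = demons_register(blob, moving, 1.0)
        assert f.similarity > 0.99

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            demons_register(np.ones((32, 32)), np.zeros((32, 32)), 1.0)

    def test_shape_mismatch_rejected(self, blob):
        with pytest.raises(ValueError):
            demons_register(blob, blob[:32], 1.0)


class TestEstimateAllFields:
    def test_reference_phase_fields_are_zero(self, mr_and_fields, crm_small_spec):
        _, fields = mr_and_fields
        to_ref, from_ref = fields[crm_small_spec.reference_phase]
        assert not np.any(to_ref.displacement)
        assert not np.any(from_ref.displacement)
        assert to_ref.direction == "to_reference"
        assert from_ref.direction == "from_reference"

    def test_forward_backward_composition(self, phantom, mr_and_fields):
        """to_reference o from_reference residual < 0.5 px on a test grid."""
        _, fields = mr_and_fields
        ps = phantom.pixel_size
        grid = (phantom.label_map > 0)
        grid &= np.logical_and.outer(np.arange(128) % 6 == 0,
                                     np.arange(128) % 6 == 0)
        for ph, (to_ref, from_ref) in fields.items():
            u, v = to_ref.displacement, from_ref.displacement
            comp = np.stack([warp_map(v[0], u, ps), warp_map(v[1], u, ps)]) + u
            mag = np.hypot(comp[0], comp[1])[grid] / ps
            assert np.percentile(mag, 95) < 0.5

    def test_fields_match_phantom_truth(self, phantom, crm_small_spec, mr_and_fields):
        """Mean endpoint error against the true deformation < 1 pixel."""
        _, fields = mr_and_fields
        ps = phantom.pixel_size
        body = phantom.label_map > 0
        for ph in crm_small_spec.phases():
            if ph == crm_small_spec.reference_phase:
                continue
            u_true = true_deformation(phantom, crm_small_spec, ph)
            v_true = invert_field(MotionField(u_true, ps)).displacement
            est = fields[ph][0].displacement
            epe = np.hypot(est[0] - v_true[0], est[1] - v_true[1])[body]
            assert epe.mean() / ps < 1.0

    def test_missing_reference_rejected(self, mr_and_fields):
        images, _ = mr_and_fields
        with pytest.raises(ValueError, match="reference"):
            estimate_all_fields(images, (9, 9), 3.0)


class TestWarping:
    def test_zero_field_identity(self, blob):
        f = MotionField.zero(blob.shape, 1.0)
        assert np.allclose(warp_image(blob, f), blob)

    def test_integer_translation_exact_interior(self, phantom):
        mu = phantom.property_map("mu")
        u = np.zeros((2,) + mu.shape)
        u[0] += 3 * phantom.pixel_size
        f = MotionField(u, phantom.pixel_size)
        out = warp_image(mu, f)
        assert np.array_equal(out[:-3], mu[3:])

    def test_round_trip_rmse(self, blob):
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        g = np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / 400.0)
        u = np.stack([2.0 * g, -1.5 * g])
        f = MotionField(u, 1.0)
        back = warp_image(warp_image(blob, f), invert_field(f))
        interior = slice(8, -8)
        num = np.sqrt(np.mean((back - blob)[interior, interior] ** 2))
        assert num / blob[interior, interior].mean() < 0.02

    def test_unknown_interpolation_rejected(self, blob):
        with pytest.raises(ValueError):
            warp_image(blob, MotionField.zero(blob.shape, 1.0), "cubic")


class TestWarpAttenuationMap:
    def test_zero_field_keeps_reference(self, phantom):
        mu = phantom.property_map("mu")
        f = MotionField.zero(mu.shape, phantom.pixel_size, "from_reference")
        assert np.allclose(warp_attenuation_map(mu, f), mu)

    def test_wrong_direction_rejected(self, phantom):
        mu = phantom.property_map("mu")
        f = MotionField.zero(mu.shape, phantom.pixel_size, "to_reference")
        with pytest.raises(ValueError, match="from_reference"):
            warp_attenuation_map(mu, f)

    def test_matches_true_phase_map(self, phantom, crm_small_spec, mr_and_fields):
        """MR-measured transport reproduces the true phase mu map (<10% NRMSE)."""
        _, fields = mr_and_fields
        mu_ref = phantom.property_map("mu")
        worst = 0.0
        for ph in crm_small_spec.phases():
            if ph == crm_small_spec.reference_phase:
                continue
            u_true = true_deformation(phantom, crm_small_spec, ph)
            mu_true = warp_map(mu_ref, u_true, phantom.pixel_size)
            mu_est = warp_attenuation_map(mu_ref, fields[ph][1])
            # normalise over the attenuating support; the air background
            # would otherwise deflate the reference mean
            sup = (mu_true > 0) | (mu_est > 0)
            nrmse = np.sqrt(np.mean((mu_est - mu_true)[sup] ** 2)) / mu_true[sup].mean()
            worst = max(worst, nrmse)
        assert worst < 0.10

    def test_value_support_preserved(self, phantom, mr_and_fields):
        _, fields = mr_and_fields
        mu_ref = phantom.property_map("mu")
        for ph, (_, from_ref) in fields.items():
            out = warp_attenuation_map(mu_ref, from_ref)
            assert out.min() >= mu_ref.min() - 1e-12
            assert out.max() <= mu_ref.max() + 1e-12


class TestAssembleStudy:
    @pytest.fixture(scope="class")
    def frames(self, rng_cls=np.random.default_rng(3)):
        return rng_cls.random((4, 32, 32))

    def test_zero_motion_mc_equals_nmc(self, frames):
        spec = MotionPhaseSpec.crm(n_cardiac=2, n_resp=1, cardiac_amplitude=0.0,
                                   resp_amplitude=0.0)
        per_phase = {ph: frames / spec.total_phases for ph in spec.phases()}
        fields = {ph: (MotionField.zero((32, 32), 3.0),
                       MotionField.zero((32, 32), 3.0, "from_reference"))
                  for ph in spec.phases()}
        nmc = assemble_study(per_phase, None, "NMC", spec)
        mc = assemble_study(per_phase, fields, "MC", spec)
        assert np.allclose(mc, nmc)

    def test_zero_motion_ga_matches_nmc_and_st(self, frames):
        spec = MotionPhaseSpec.crm(n_cardiac=2, n_resp=1, cardiac_amplitude=0.0,
                                   resp_amplitude=0.0)
        per_phase = {ph: frames / spec.total_phases for ph in spec.phases()}
        ga = assemble_study(per_phase, None, "GA", spec)
        nmc = assemble_study(per_phase, None, "NMC", spec)
        st = assemble_study({}, None, "ST", spec, st_frames=frames)
        assert np.allclose(ga, nmc) and np.allclose(nmc, st)

    def test_nmc_count_bookkeeping_is_linear(self, frames, rng):
        spec = MotionPhaseSpec.crm(n_cardiac=2, n_resp=2, resp_amplitude=5.0)
        per_phase = {ph: rng.random((4, 32, 32)) for ph in spec.phases()}
        nmc = assemble_study(per_phase, None, "NMC", spec)
        assert np.allclose(nmc, sum(per_phase.values()))

    def test_missing_phase_reported(self, frames):
        spec = MotionPhaseSpec.crm(n_cardiac=2, n_resp=2, resp_amplitude=5.0)
        per_phase = {ph: frames for ph in spec.phases() if ph != (1, 1)}
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            assemble_study(per_phase, None, "NMC", spec)

    def test_unknown_mode_rejected(self, frames):
        with pytest.raises(ValueError, match="mode"):
            assemble_study({}, None, "XYZ", MotionPhaseSpec.static())


def test_wall_thickness_ordering_noise_free(phantom, crm_small_spec, mr_and_fields,
                                            schedule, aif):
    """Apparent wall FWHM on a radial profile: NMC > MC >= ST (noise-free)."""
    from petmoco import ProjectionGeometry
    from petmoco.evaluation import line_profile
    from petmoco.pipeline import (_st_series, reconstruct_studies,
                                  simulate_mean_sinograms)
    import petmoco.pipeline as pl
    import unittest.mock as mock

    geom = ProjectionGeometry()
    _, fields = mr_and_fields
    sim = simulate_mean_sinograms(phantom, crm_small_spec, schedule, aif, geom)
    st = _st_series(sim, phantom, crm_small_spec, schedule, geom, "hann")
    with mock.patch.object(pl, "add_poisson_noise", lambda m, rng: np.asarray(m)):
        series = reconstruct_studies(sim, phantom, crm_small_spec, schedule, geom,
                                     fields, 1, 0, "hann")

    cy, cx = phantom.lv_center

    def wall_fwhm(img):
        # radial profile upward through the anterior wall (max resp blur)
        prof = line_profile(img, (cy, cx), (cy - 14, cx))
        prof = prof - prof.min()
        half = prof.max() / 2.0
        above = np.where(prof >= half)[0]
        return above[-1] - above[0] + 1

    last = schedule.n_frames - 1
    w_st = wall_fwhm(st[last])
    w_nmc = wall_fwhm(series["NMC"][0][last])
    w_mc = wall_fwhm(series["MC"][0][last])
    assert w_nmc > w_mc >= w_st
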