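"""Projection physics, OSEM reconstruction and bias analysis."""

import numpy as np
import pytest

from dixbone import Image3D
from dixbone.mumap import MuMap
from dixbone import petsim
from dixbone.petsim import (
    ProjectionGeometry,
    ReconParams,
    Sinogram,
    attenuation_factors,
    back_project,
    forward_project,
    line_profile,
    osem_reconstruct,
    poisson_log_likelihood,
    relative_difference_map,
    shell_profile,
    simulate_counts,
)

SP = 2.0


def disc_image(n=64, radius_mm=40.0, value=3.0, nz=3, active_slice=1):
    xx, yy = np.meshgrid(*(np.arange(n) - (n - 1) / 2,) * 2, indexing="ij")
    disc = (xx * SP) ** 2 + (yy * SP) ** 2 <= radius_mm**2
    data = np.zeros((n, n, nz))
    data[:, :, active_slice][disc] = value
    return Image3D(data, spacing=(SP, SP, SP)), disc


@pytest.fixture(scope="module")
def geom():
    return ProjectionGeometry(63, 64, SP, (1,))


class TestProjector:
    def test_central_ray_chord_length(self, geom):
        im, _ = disc_image()
        sino = forward_project(im, geom)
        expected = 2 * 40.0 * 3.0
        central = sino.data[:, 31:33, 0]
        assert np.all(np.abs(central - expected) <= 0.02 * expected)

    def test_zero_image_projects_to_zero(self, geom):
        im = Image3D(np.zeros((64, 64, 3)), spacing=(SP, SP, SP))
        assert np.all(forward_project(im, geom).data == 0)

    def test_linearity(self, geom, rng):
        a = Image3D(rng.random((64, 64, 3)), spacing=(SP, SP, SP))
        b = a.with_data(rng.random(a.shape))
        lhs = forward_project(a.with_data(2 * a.data + 3 * b.data), geom).data
        rhs = 2 * forward_project(a, geom).data + 3 * forward_project(b, geom).data
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_adjointness(self, geom, rng):
        """<A x, y> == <x, A' y>: the back-projector is the exact transpose."""
        x = Image3D(rng.random((64, 64, 3)), spacing=(SP, SP, SP))
        Ax = forward_project(x, geom)
        y = rng.random(Ax.data.shape)
        Aty = back_project(Sinogram(y, "line_integrals", geom), x)
        lhs = float(np.sum(Ax.data * y))
        rhs = float(np.sum(x.data * Aty.data))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(4, 64, SP, (0,))


class TestAttenuation:
    def test_ten_cm_soft_tissue_closed_form(self, geom):
        """10 cm of mu=0.10 tissue: survival e^-1, ACF e."""
        im, disc = disc_image(radius_mm=50.0, value=0.10)
        acf = attenuation_factors(MuMap.from_truth(im), geom)
        assert np.allclose(acf.data[:, 31:33, 0], np.e, rtol=0.02)

    def test_zero_mu_gives_unit_acf(self, geom):
        im = Image3D(np.zeros((64, 64, 3)), spacing=(SP, SP, SP))
        assert np.allclose(attenuation_factors(
            MuMap.from_truth(im), geom).data, 1.0)

    def test_bone_path_multiplies_survival(self, geom):
        """Adding 12 mm of bone along a line scales survival by
        exp(-0.143 * 1.2) ~ 0.842 — the physical origin of the cortical
        underestimation."""
        soft, disc = disc_image(radius_mm=50.0, value=0.10)
        bone = soft.with_data(soft.data.copy())
        # 12 mm bone slab crossing the centre column
        bone.data[29:35, :, 1] = np.where(
            disc[29:35, :], 0.143, bone.data[29:35, :, 1])
        a_soft = attenuation_factors(MuMap.from_truth(soft), geom)
        a_bone = attenuation_factors(MuMap.from_truth(bone), geom)
        # angle-0 rays run along x and cross the 12 mm slab transversally
        ratio = (1 / a_bone.data[0, 31, 0]) / (1 / a_soft.data[0, 31, 0])
        assert np.isclose(ratio, np.exp(-(0.143 - 0.10) * 1.2), rtol=0.02)


class TestCounts:
    def test_poisson_total_near_requested(self, geom):
        im, _ = disc_image()
        mu = MuMap.from_truth(im.with_data(np.zeros(im.shape)))
        total = 200_000
        counts = simulate_counts(im, mu, geom, total_counts=total, seed=9)
        assert abs(counts.data.sum() - total) <= 3 * np.sqrt(total)

    def test_zero_emission_gives_zero_counts(self, geom):
        im = Image3D(np.zeros((64, 64, 3)), spacing=(SP, SP, SP))
        mu = MuMap.from_truth(im)
        counts = simulate_counts(im, mu, geom, total_counts=None, seed=0)
        assert np.all(counts.data == 0)

    def test_seeds_change_realization_not_expectation(self, geom):
        im, _ = disc_image()
        mu = MuMap.from_truth(im.with_data(np.zeros(im.shape)))
        c1 = simulate_counts(im, mu, geom, total_counts=100_000, seed=1)
        c2 = simulate_counts(im, mu, geom, total_counts=100_000, seed=2)
        c1b = simulate_counts(im, mu, geom, total_counts=100_000, seed=1)
        assert not np.array_equal(c1.data, c2.data)
        assert np.array_equal(c1.data, c1b.data)
        assert np.isclose(c1.data.sum(), c2.data.sum(), rtol=0.02)


class TestOSEM:
    def test_uniform_disc_recovered_without_attenuation(self, geom):
        im, disc = disc_image()
        mu0 = MuMap.from_truth(im.with_data(np.zeros(im.shape)))
        counts = simulate_counts(im, mu0, geom, total_counts=None,
                                 noiseless=True)
        acf1 = Sinogram(np.ones_like(counts.data), "acf", geom)
        rec = osem_reconstruct(counts, acf1, ReconParams(), grid=im)
        interior = np.zeros(im.shape, bool)
        xx, yy = np.meshgrid(*(np.arange(64) - 31.5,) * 2, indexing="ij")
        interior[:, :, 1] = (xx * SP) ** 2 + (yy * SP) ** 2 <= (40.0 - 6) ** 2
        assert abs(rec.data[interior].mean() - 3.0) <= 0.03 * 3.0

    def test_uniform_disc_recovered_with_true_attenuation(self, geom):
        im, disc = disc_image()
        mu = im.with_data(np.where(im.data > 0, 0.10, 0.0))
        mt = MuMap.from_truth(mu)
        counts = simulate_counts(im, mt, geom, total_counts=None,
                                 noiseless=True)
        rec = osem_reconstruct(counts, attenuation_factors(mt, geom),
                               ReconParams(), grid=im)
        interior = np.zeros(im.shape, bool)
        xx, yy = np.meshgrid(*(np.arange(64) - 31.5,) * 2, indexing="ij")
        interior[:, :, 1] = (xx * SP) ** 2 + (yy * SP) ** 2 <= (40.0 - 6) ** 2
        assert abs(rec.data[interior].mean() - 3.0) <= 0.03 * 3.0

    def test_output_nonnegative_on_noisy_input(self, geom):
        im, _ = disc_image()
        mu0 = MuMap.from_truth(im.with_data(np.zeros(im.shape)))
        counts = simulate_counts(im, mu0, geom, total_counts=20_000, seed=3)
        acf1 = Sinogram(np.ones_like(counts.data), "acf", geom)
        rec = osem_reconstruct(counts, acf1, ReconParams(), grid=im)
        assert rec.data.min() >= 0
        assert np.all(np.isfinite(rec.data))

    def test_full_iteration_log_likelihood_nondecreasing(self, geom):
        im, _ = disc_image()
        mu = MuMap.from_truth(im.with_data(np.where(im.data > 0, 0.10, 0.0)))
        counts = simulate_counts(im, mu, geom, total_counts=None,
                                 noiseless=True)
        acf = attenuation_factors(mu, geom)
        lls = []
        for its in (1, 2, 3):
            rec = osem_reconstruct(
                counts, acf,
                ReconParams(iterations=its, postfilter_fwhm_mm=0.0), grid=im)
            lls.append(poisson_log_likelihood(counts, acf, rec))
        assert lls[0] <= lls[1] + 1e-6 * abs(lls[1])
        assert lls[1] <= lls[2] + 1e-6 * abs(lls[2])


class TestBiasAnalysis:
    def test_relative_difference_formula(self):
        shape = (4, 4, 1)
        mask = Image3D(np.ones(shape))
        a = Image3D(np.full(shape, 14.56))
        b = Image3D(np.full(shape, 13.16))
        rd = relative_difference_map(a, b, mask)
        assert np.allclose(rd.data, 10.6383, atol=1e-3)
        assert np.allclose(relative_difference_map(
            b.with_data(1.2 * b.data), b, mask).data, 20.0)
        assert np.all(relative_difference_map(b, b, mask).data == 0)

    def test_zero_denominator_inside_mask_rejected(self):
        a = Image3D(np.ones((3, 3, 1)))
        b = Image3D(np.zeros((3, 3, 1)))
        with pytest.raises(ValueError):
            relative_difference_map(a, b, Image3D(np.ones((3, 3, 1))))

    def test_nan_outside_mask(self):
        a = Image3D(np.ones((4, 4, 1)))
        mask = a.with_data(np.zeros(a.shape))
        mask.data[1, 1, 0] = 1
        rd = relative_difference_map(a, a, mask)
        assert np.isnan(rd.data[0, 0, 0]) and rd.data[1, 1, 0] == 0

    def test_line_profile_constant_is_flat(self):
        im = Image3D(np.full((8, 8, 2), 5.0))
        assert np.all(line_profile(im, 1) == 5.0)
        with pytest.raises(ValueError):
            line_profile(im, 5)

    def test_shell_profile_matches_radial_symmetry(self):
        """For a radially symmetric field, shell averages reproduce the
        radial function."""
        n = 64
        xx, yy = np.meshgrid(*(np.arange(n) - (n - 1) / 2,) * 2, indexing="ij")
        r = np.hypot(xx, yy) * SP
        field = np.zeros((n, n, 1))
        mask = np.zeros((n, n, 1))
        inside = r <= 50.0
        field[:, :, 0][inside] = (r[inside] / 50.0) ** 2
        mask[:, :, 0][inside] = 1
        centres, means = shell_profile(
            Image3D(field, spacing=(SP, SP, SP)),
            Image3D(mask, spacing=(SP, SP, SP)), n_shells=10)
        # normalised radius tracks r/50; shell means follow rho^2
        assert np.all(np.diff(means) > 0)
        assert np.allclose(means, centres**2, atol=0.12)


@pytest.fixture(scope="module")
def mini_run():
    import dixbone as dx
    from dixbone import phantom as phm
    from dixbone.mumap import dixon_mumap, compose_dixon_bone

    ph = dx.build_head_phantom((64, 64, 64), 3.0, 8.0, seed=5)
    emission = phm.render_emission(ph)
    mu_true = MuMap.from_truth(phm.true_mumap_image(ph))
    water, fat = phm.render_dixon(ph, noise_sd=0.0, seed=0)
    dixon = dixon_mumap(water, fat)
    dxbone = compose_dixon_bone(
        dixon, ph.mask(phm.SKULL))   # true-skull mask: physics only
    geom = petsim.default_geometry(emission, n_angles=96, n_central_slices=3)
    counts = simulate_counts(emission, mu_true, geom, total_counts=None,
                             noiseless=True)
    params = ReconParams()
    recs = {
        name: osem_reconstruct(
            counts, attenuation_factors(mm, geom), params, grid=emission)
        for name, mm in (("truth", mu_true), ("dx", dixon),
                         ("dxbone", dxbone))
    }
    sel = np.zeros(emission.shape, bool)
    sel[:, :, list(geom.slices)] = True
    brain = emission.with_data(
        ((ph.brain_mask.data > 0) & sel).astype(np.uint8))
    return ph, recs, brain


class TestEndToEndBias:
    """Miniature of the headline experiment: bone-free attenuation
    correction underestimates activity inside the skull, worst at the rim."""

    def test_bone_free_correction_underestimates_active_tissue(self, mini_run):
        """Every GM/WM voxel reconstructs lower without bone in the mu-map.

        Cold structures (ventricular CSF, emission 1/30 of GM) are excluded:
        there the mismatch redistributes counts and can locally flip the
        sign, while all metabolically active tissue is underestimated."""
        from dixbone import phantom as phm
        ph, recs, brain = mini_run
        m = (brain.data > 0) & np.isin(ph.labels.data, (phm.GM, phm.WM))
        assert np.all(recs["dx"].data[m] < recs["truth"].data[m])

    def test_bias_profile_rises_from_centre_to_rim(self, mini_run):
        ph, recs, brain = mini_run
        rd = relative_difference_map(recs["dxbone"], recs["dx"], brain)
        centres, means = shell_profile(rd, brain, n_shells=5)
        assert means[-1] > means[0]
        assert means[-1] > 10.0          # strong cortical effect
        assert np.all(np.diff(means[1:]) > -0.5)   # near-monotone rise
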