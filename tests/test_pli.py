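import numpy as np
import pytest

from fiberphantom import (
    Fiber,
    OpticsParams,
    Phantom,
    ValidationError,
    VoxelVolume,
    add_noise,
    downsample_blur,
    fill_bundle,
    orientation_to_color,
    recover_orientation,
    simulate_measurement,
    voxelize,
)
from fiberphantom.pli import closed_form_intensity


def homogeneous_volume(phi, alpha, nz=60):
    u = np.array(
        [np.cos(alpha) * np.cos(phi), np.cos(alpha) * np.sin(phi), np.sin(alpha)]
    )
    orient = np.tile(u, (1, 1, nz, 1))
    return VoxelVolume(orient, np.ones((1, 1, nz), bool), 1.0)


def delta_total(params, alpha, thickness_um):
    return (
        2 * np.pi * thickness_um / params.wavelength_um
        * params.birefringence * np.cos(alpha) ** 2
    )


class TestVoxelize:
    def test_straight_fiber_disc_occupancy_and_orientation(self):
        # radius 2 µm -> disc area 4π ≈ 12.6 voxels per slice
        f = Fiber([[0, 0, 0, 2.0], [20, 0, 0, 2.0]], label="f")
        p = Phantom()
        p.add(f)
        vol = voxelize(p, ((5.0, -4.0, -4.0), (15.0, 4.0, 4.0)), 1.0)
        per_slice = vol.tissue.sum(axis=(1, 2))
        assert np.all((per_slice >= 9) & (per_slice <= 16))
        occupied = vol.orientation[vol.tissue]
        np.testing.assert_allclose(
            occupied, np.broadcast_to([1.0, 0.0, 0.0], occupied.shape)
        )

    def test_empty_region_is_background(self):
        f = Fiber([[0, 0, 0, 1.0], [10, 0, 0, 1.0]], label="f")
        p = Phantom()
        p.add(f)
        vol = voxelize(p, ((100.0, 100.0, 100.0), (110.0, 110.0, 110.0)), 1.0)
        assert not vol.tissue.any()

    def test_crossing_fibers_resolved_by_nearest_axis(self):
        pa = Phantom()
        pa.add(Fiber([[-10, 0, 0, 2.0], [10, 0, 0, 2.0]], label="along_x"))
        pa.add(Fiber([[0, -10, 0.5, 2.0], [0, 10, 0.5, 2.0]], label="along_y"))
        bbox = ((-8.0, -8.0, -4.0), (8.0, 8.0, 4.0))
        vol = voxelize(pa, bbox, 1.0)

        # independent point-in-capsule oracle
        centers = [
            bbox[0][k] + (np.arange(vol.shape[k]) + 0.5) for k in range(3)
        ]
        fibers = [f for _, f in pa.iter_fibers()]
        for idx in np.argwhere(vol.tissue)[::7]:
            c = np.array([centers[k][idx[k]] for k in range(3)])
            dists = []
            for f in fibers:
                p0, p1 = f.xyz[0], f.xyz[1]
                d = p1 - p0
                t = np.clip((c - p0) @ d / (d @ d), 0, 1)
                dists.append(np.linalg.norm(c - (p0 + t * d)))
            winner = fibers[int(np.argmin(dists))]
            assert min(dists) < 2.0
            tangent = (winner.xyz[1] - winner.xyz[0]) / np.linalg.norm(
                winner.xyz[1] - winner.xyz[0]
            )
            np.testing.assert_allclose(
                vol.orientation[tuple(idx)], tangent, atol=1e-9
            )

    def test_invalid_voxel_size(self):
        p = Phantom()
        p.add(Fiber([[0, 0, 0, 1.0], [1, 0, 0, 1.0]], label="f"))
        with pytest.raises(ValidationError):
            voxelize(p, ((0, 0, 0), (1, 1, 1)), -1.0)


class TestSimulate:
    def test_background_column_gives_half_intensity(self):
        vol = VoxelVolume(np.zeros((2, 2, 5, 3)), np.zeros((2, 2, 5), bool))
        params = OpticsParams(absorption_per_mm=0.0)
        stack = simulate_measurement(vol, params)
        np.testing.assert_allclose(stack, params.intensity / 2.0, rtol=1e-12)

    def test_vertical_fiber_has_no_modulation(self):
        vol = homogeneous_volume(0.0, np.pi / 2)
        stack = simulate_measurement(vol, OpticsParams())
        np.testing.assert_allclose(
            stack, np.broadcast_to(stack[0], stack.shape), rtol=1e-12
        )

    def test_homogeneous_column_matches_closed_form(self):
        params = OpticsParams()
        phi = np.deg2rad(30.0)
        vol = homogeneous_volume(phi, 0.0)
        stack = simulate_measurement(vol, params)
        rho = np.array(params.rotation_angles)
        I_T = params.intensity * np.exp(-params.absorption_per_um * 60)
        expected = closed_form_intensity(rho, phi, delta_total(params, 0.0, 60), I_T)
        np.testing.assert_allclose(stack[:, 0, 0], expected, rtol=1e-9)
        # modulation amplitude from the second discrete harmonic
        n = rho.size
        a2 = 2 / n * np.sum(stack[:, 0, 0] * np.cos(2 * rho))
        b2 = 2 / n * np.sum(stack[:, 0, 0] * np.sin(2 * rho))
        assert np.hypot(a2, b2) == pytest.approx(
            I_T / 2 * abs(np.sin(delta_total(params, 0.0, 60))), rel=1e-9
        )

    def test_chain_equals_closed_form_for_random_columns(self, rng):
        # 1000 random (phi, alpha, thickness) triples, batched as columns of
        # one volume with per-column tissue depth
        n = 1000
        nz = 60
        phi = rng.uniform(0, np.pi, n)
        alpha = rng.uniform(0, np.pi / 2, n)
        depth = rng.integers(1, nz + 1, n)
        orient = np.zeros((n, 1, nz, 3))
        tissue = np.zeros((n, 1, nz), bool)
        for i in range(n):
            u = np.array([
                np.cos(alpha[i]) * np.cos(phi[i]),
                np.cos(alpha[i]) * np.sin(phi[i]),
                np.sin(alpha[i]),
            ])
            orient[i, 0, : depth[i]] = u
            tissue[i, 0, : depth[i]] = True
        params = OpticsParams()
        stack = simulate_measurement(VoxelVolume(orient, tissue), params)
        rho = np.array(params.rotation_angles)
        for i in range(n):
            I_T = params.intensity * np.exp(-params.absorption_per_um * depth[i])
            expected = closed_form_intensity(
                rho, phi[i], delta_total(params, alpha[i], depth[i]), I_T
            )
            np.testing.assert_allclose(stack[:, i, 0], expected, rtol=1e-9,
                                       atol=1e-9 * params.intensity)

    def test_stokes_stay_physical_throughout_propagation(self, rng):
        vol = homogeneous_volume(np.deg2rad(55.0), np.deg2rad(20.0))
        worst = []

        def audit(S):
            pol = np.linalg.norm(S[..., 1:], axis=-1)
            worst.append(float((pol - S[..., 0]).max()))

        simulate_measurement(vol, OpticsParams(), on_step=audit)
        assert len(worst) > 60
        assert max(worst) <= 1e-9 * OpticsParams().intensity


class TestDownsampleBlur:
    def test_constant_image_unchanged(self):
        params = OpticsParams(pixel_size_um=4.0)
        stack = np.full((3, 16, 16), 7.5)
        out = downsample_blur(stack, params, voxel_size=1.0)
        assert out.shape == (3, 4, 4)
        np.testing.assert_allclose(out, 7.5, rtol=1e-12)

    def test_mean_preserved_on_random_images(self, rng):
        params = OpticsParams(pixel_size_um=5.0)
        stack = rng.uniform(0, 100, size=(2, 40, 40))
        out = downsample_blur(stack, params, voxel_size=1.0)
        np.testing.assert_allclose(out.mean(), stack.mean(), rtol=1e-6)

    def test_default_factor_is_twenty(self):
        params = OpticsParams()
        out = downsample_blur(np.ones((1, 40, 40)), params, voxel_size=1.0)
        assert out.shape == (1, 2, 2)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValidationError, match="integer multiple"):
            downsample_blur(np.ones((1, 12, 12)), OpticsParams(pixel_size_um=2.5),
                            voxel_size=1.0)


class TestNoise:
    def test_disabled_noise_is_identity(self):
        params = OpticsParams(noise_gain=0.0)
        stack = np.random.default_rng(0).uniform(100, 200, (3, 4, 4))
        np.testing.assert_array_equal(add_noise(stack, params, 1), stack)

    def test_same_seed_reproduces_stack(self):
        params = OpticsParams()
        stack = np.full((9, 5, 5), 13000.0)
        a = add_noise(stack, params, 42)
        b = add_noise(stack, params, 42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, stack)

    def test_unbiased_mean_over_replicates(self):
        params = OpticsParams()
        value = 13000.0
        reps = add_noise(np.full((100000, 1, 1), value), params, 7)
        se = np.sqrt(params.noise_gain * value / reps.size)
        assert abs(reps.mean() - value) < 3 * se


class TestRecover:
    @pytest.mark.parametrize("phi_deg, alpha_deg", [(75.0, 0.0), (10.0, 40.0),
                                                    (150.0, 70.0)])
    def test_inverts_homogeneous_column(self, phi_deg, alpha_deg):
        params = OpticsParams()
        phi, alpha = np.deg2rad(phi_deg), np.deg2rad(alpha_deg)
        stack = simulate_measurement(homogeneous_volume(phi, alpha), params)
        fom = recover_orientation(stack, params)
        assert fom.mask[0, 0]
        assert abs(fom.direction[0, 0] - phi) < 1e-4
        assert abs(fom.inclination[0, 0] - alpha) < 1e-3

    def test_vertical_fibers_masked_as_undefined(self):
        params = OpticsParams()
        stack = simulate_measurement(homogeneous_volume(0.3, np.pi / 2), params)
        fom = recover_orientation(stack, params)
        assert not fom.mask[0, 0]

    def test_background_masked(self):
        params = OpticsParams()
        vol = VoxelVolume(np.zeros((1, 1, 5, 3)), np.zeros((1, 1, 5), bool))
        fom = recover_orientation(simulate_measurement(vol, params), params)
        assert not fom.mask.any()

    def test_too_few_angles_rejected(self):
        params = OpticsParams()
        with pytest.raises(ValidationError):
            recover_orientation(
                np.ones((2, 1, 1)),
                OpticsParams(rotation_angles=(0.0, np.pi / 2, 0.0)),
            )

    def test_symmetric_crossing_recovers_bisector(self):
        # two equal-thickness in-plane layers at ±25°: the harmonic
        # estimator returns their bisector (0°)
        params = OpticsParams()
        nz = 60
        orient = np.zeros((1, 1, nz, 3))
        for z in range(nz):
            ang = np.deg2rad(25.0) if z % 2 == 0 else np.deg2rad(-25.0)
            orient[0, 0, z] = [np.cos(ang), np.sin(ang), 0.0]
        vol = VoxelVolume(orient, np.ones((1, 1, nz), bool))
        fom = recover_orientation(simulate_measurement(vol, params), params)
        err = np.degrees(min(fom.direction[0, 0], np.pi - fom.direction[0, 0]))
        assert err < 2.0


class TestEndToEnd:
    def test_straight_bundle_orientation_recovered(self):
        # build a filled straight bundle at known (phi, alpha), voxelize a
        # 60 µm section, simulate, blur/downsample and recover
        phi, alpha = np.deg2rad(30.0), np.deg2rad(10.0)
        direction = np.array(
            [np.cos(alpha) * np.cos(phi), np.cos(alpha) * np.sin(phi),
             np.sin(alpha)]
        )
        n = 9
        pts = np.outer(np.linspace(-110.0, 110.0, n), direction)
        envelope = Fiber(np.column_stack([pts, np.full(n, 45.0)]), "bundle")
        filled = fill_bundle(envelope, r_fiber=1.5, spacing=3.3)
        params = OpticsParams(pixel_size_um=10.0)
        vol = voxelize(
            Phantom(filled), ((-60.0, -60.0, -30.0), (60.0, 60.0, 30.0)), 1.0
        )
        stack = simulate_measurement(vol, params)
        stack = downsample_blur(stack, params, vol.voxel_size)
        fom = recover_orientation(stack, params)
        # central pixels are fully tissue through the section
        c = fom.direction.shape[0] // 2
        sel = np.s_[c - 2 : c + 2, c - 2 : c + 2]
        assert fom.mask[sel].all()
        phi_err = np.abs(fom.direction[sel] - phi)
        phi_err = np.minimum(phi_err, np.pi - phi_err)
        assert np.degrees(np.median(phi_err)) < 1.0
        alpha_err = np.abs(fom.inclination[sel] - alpha)
        assert np.degrees(np.median(alpha_err)) < 3.0


class TestColor:
    def test_axis_vectors_in_rgb_mode(self):
        np.testing.assert_allclose(
            orientation_to_color(np.array([0.0, 0.0, 1.0]), "rgb"), [0, 0, 1]
        )
        np.testing.assert_allclose(
            orientation_to_color(np.array([1.0, 0.0, 0.0]), "rgb"), [1, 0, 0]
        )

    @pytest.mark.parametrize("mode", ["rgb", "hsv"])
    def test_antipodal_symmetry(self, mode, rng):
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        np.testing.assert_allclose(
            orientation_to_color(v, mode), orientation_to_color(-v, mode),
            atol=1e-12,
        )

    def test_hue_continuous_across_direction_wraparound(self):
        # sweep the in-plane direction through 0/π: hue must wrap without a
        # visible jump (circular hue distance < 0.02 between adjacent steps)
        phis = np.linspace(0, np.pi, 361)
        v = np.column_stack([np.cos(phis), np.sin(phis), np.zeros_like(phis)])
        rgb = orientation_to_color(v, "hsv")
        jumps = np.abs(np.diff(rgb, axis=0)).max(axis=1)
        assert jumps.max() < 0.02
        np.testing.assert_allclose(rgb[0], rgb[-1], atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            orientation_to_color(np.zeros(3), "rgb")
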