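"""Rotational power spectra, stoichiometry detection, averaging."""

import math

import numpy as np
import pytest

import poremorph as pm
from poremorph.symmetry import (_center_by_twofold, apply_transform,
                                polar_rewrap, polar_unwrap,
                                rotational_power_spectrum)
from conftest import crest_modulation_amplitude, render_ring


def brute_force_power(signal: np.ndarray) -> np.ndarray:
    """Direct DFT-sum power per angular order (oracle)."""
    n = len(signal)
    k_max = n // 2
    power = np.empty(k_max + 1)
    theta = 2 * math.pi * np.arange(n) / n
    for k in range(k_max + 1):
        c = np.sum(signal * np.exp(-1j * k * theta)) / n
        power[k] = abs(c) ** 2
    return power


class TestPolarUnwrap:
    def test_radially_symmetric_bump_constant_rows(self):
        # Bilinear sampling of a smooth radial profile: residual angular
        # variation is pure interpolation error, far below the signal.
        yy, xx = np.mgrid[0:161, 0:161] * 0.25
        rr = np.hypot(yy - 20, xx - 20)
        t = pm.Topograph(3.0 * np.exp(-((rr - 10) / 3) ** 2), (0.25, 0.25))
        polar = polar_unwrap(t, (20.0, 20.0), (8.0, 12.0), 128, 8)
        assert np.all(polar.std(axis=0) < 1e-3 * polar.mean())

    def test_ring_gives_n_periods(self, ring_topo):
        c = (ring_topo.extent_nm[1] / 2, ring_topo.extent_nm[0] / 2)
        polar = polar_unwrap(ring_topo, c, (11.8, 14.5), 240, 8)
        power = rotational_power_spectrum(polar)
        assert np.argmax(power[1:]) + 1 == 30

    def test_rewrap_round_trip(self, ring_topo):
        c = (ring_topo.extent_nm[1] / 2, ring_topo.extent_nm[0] / 2)
        r_range = (9.0, 16.0)
        polar = polar_unwrap(ring_topo, c, r_range, 720, 64)
        back = polar_rewrap(polar, c, r_range, ring_topo.shape,
                            ring_topo.pixel_size)
        mask = ~np.isnan(back)
        assert mask.sum() > 1000
        err = np.abs(back[mask] - ring_topo.heights[mask])
        assert np.quantile(err, 0.99) < 0.1

    def test_annulus_outside_image_rejected(self, ring_topo):
        with pytest.raises(ValueError):
            polar_unwrap(ring_topo, (5.0, 5.0), (2.0, 50.0))


class TestRotationalPowerSpectrum:
    def test_pure_harmonic_concentrates_power(self):
        theta = 2 * math.pi * np.arange(160) / 160
        polar = np.cos(24 * theta)[:, None] * np.ones((1, 4))
        power = rotational_power_spectrum(polar)
        assert power[24] / power[1:].sum() > 0.99

    def test_constant_signal_zero_power(self):
        power = rotational_power_spectrum(np.full((160, 4), 2.5))
        assert np.all(power[1:] < 1e-24)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            polar = rng.normal(0, 1, (96, 6))
            mine = rotational_power_spectrum(polar)
            oracle = brute_force_power(polar.mean(axis=1))
            scale = max(oracle.max(), 1e-30)
            assert np.abs(mine - oracle).max() / scale < 1e-10


class TestDetectStoichiometry:
    def test_noiseless_ring_detected(self, ring_topo):
        rec = pm.measure_particle(ring_topo, None)
        res = pm.particle_stoichiometry(ring_topo, rec.center,
                                        rec.crest_diameter / 2)
        assert res.detected_n == 30
        assert res.distinct_peak

    def test_white_noise_rarely_distinct(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = pm.Topograph(rng.normal(0, 0.3, (82, 82)), (0.5, 0.5))
            res = pm.particle_stoichiometry(t, (20.5, 20.5), 13.0,
                                            refine_center=False)
            hits += res.distinct_peak
        assert hits <= 5

    def test_snr3_mostly_correct(self):
        n = 22
        amp = crest_modulation_amplitude(n)
        correct = 0
        for seed in range(40):
            topo, p = render_ring(n, noise_sd=amp / 3, rng_seed=seed,
                                  phase_deg=seed * 7.3)
            rec = pm.measure_particle(topo, None)
            res = pm.particle_stoichiometry(topo, rec.center,
                                            p.crest_diameter / 2)
            correct += res.detected_n == n
        assert correct >= 38

    def test_range_and_flag_semantics(self):
        power = np.zeros(41)
        power[25] = 1.0
        res = pm.detect_stoichiometry(power)
        assert res.detected_n == 25 and res.distinct_peak
        flat = np.ones(41)
        res = pm.detect_stoichiometry(flat)
        assert res.detected_n is None and not res.distinct_peak


class TestAlignToReference:
    def test_identity(self, ring_topo):
        tf, corr = pm.align_to_reference(ring_topo.heights,
                                         ring_topo.heights)
        assert corr > 0.9999
        angle = tf["angle_deg"] % 360
        assert min(angle, 360 - angle) < 0.1
        assert np.hypot(*tf["shift_px"]) < 0.1

    def test_rotation_recovery_on_asymmetric_image(self):
        p = pm.ParticleSpec(center=(0.0, 0.0), shape="arc", n_subunits=30,
                            arc_span=11)
        topo = pm.level_and_zero(pm.render_scene(
            pm.scene_for_particle(p, pixel_size=0.5)))
        ref = topo.heights
        img = apply_transform(ref, 37.0, (0.0, 0.0))
        tf, corr = pm.align_to_reference(img, ref, rotation_step_deg=3.0)
        recovered = tf["angle_deg"] % 360
        assert min(abs(recovered - 323), abs(recovered - (-37) % 360)) <= 3.0
        assert corr > 0.98

    def test_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(5)
        ref = np.zeros((32, 32))
        yy, xx = np.mgrid[0:32, 0:32]
        for _ in range(4):  # asymmetric blob pattern
            cy, cx, s = rng.uniform(8, 24), rng.uniform(8, 24), rng.uniform(2, 4)
            ref += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        img = apply_transform(ref, 25.0, (2.0, -1.0))
        tf, corr = pm.align_to_reference(img, ref, rotation_step_deg=5.0,
                                         max_shift_px=4.0)
        # Oracle: coarse exhaustive grid over rotations x integer shifts.
        best = -2.0
        for ang in np.arange(0, 360, 5.0):
            rot = apply_transform(img, ang, (0.0, 0.0), order=1)
            for dy in range(-4, 5):
                for dx in range(-4, 5):
                    shifted = np.roll(np.roll(rot, dy, axis=0), dx, axis=1)
                    a = shifted.ravel() - shifted.mean()
                    b = ref.ravel() - ref.mean()
                    c = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                    best = max(best, c)
        assert corr >= best - 0.02

    def test_empty_search_rejected(self, ring_topo):
        with pytest.raises(ValueError):
            pm.align_to_reference(ring_topo.heights, ring_topo.heights,
                                  rotation_step_deg=0.0)


class TestCorrelationAverage:
    @pytest.fixture(scope="class")
    def template(self):
        topo, _ = render_ring(24)
        return topo.heights

    def test_copies_retained_average_matches_template(self, template):
        rng = np.random.default_rng(0)
        members = [apply_transform(template, rng.uniform(0, 360),
                                   tuple(rng.uniform(-3, 3, 2)))
                   for _ in range(6)]
        ca = pm.correlation_average(members, stoichiometry=24)
        assert ca.rejected_ids == []
        _, corr = pm.align_to_reference(ca.average, template)
        assert corr >= 0.999

    def test_noise_member_rejected_at_threshold(self, template):
        rng = np.random.default_rng(1)
        members = [apply_transform(template, rng.uniform(0, 360),
                                   tuple(rng.uniform(-3, 3, 2)))
                   for _ in range(10)]
        members.append(rng.normal(0, 1.0, template.shape))
        ca = pm.correlation_average(members, reject_below=0.9)
        assert ca.rejected_ids == [10]
        assert all(c >= 0.9 for c in ca.correlations.values())

    def test_mean_retained_correlation_nondecreasing(self, template):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            members = [apply_transform(template, rng.uniform(0, 360),
                                       tuple(rng.uniform(-2, 2, 2)))
                       + rng.normal(0, 0.15, template.shape)
                       for _ in range(6)]
            ca = pm.correlation_average(members)
            h = ca.mean_correlation_history
            assert all(b >= a - 1e-3 for a, b in zip(h, h[1:]))

    def test_permutation_invariance(self, template):
        rng = np.random.default_rng(2)
        members = [apply_transform(template, rng.uniform(0, 360),
                                   tuple(rng.uniform(-2, 2, 2)))
                   + rng.normal(0, 0.05, template.shape) for _ in range(5)]
        ca1 = pm.correlation_average(members)
        perm = [2, 0, 4, 1, 3]
        ca2 = pm.correlation_average([members[i] for i in perm])
        assert sorted(perm[i] for i in ca2.member_ids) \
            == sorted(ca1.member_ids)
        _, corr = pm.align_to_reference(ca2.average, ca1.average)
        assert corr > 0.999

    def test_all_rejected_is_error(self, template):
        # An unreachable threshold rejects every member, including the one
        # seeding the reference (whose self-correlation is < 1 only by
        # interpolation error), so the threshold is set above 1.
        rng = np.random.default_rng(3)
        members = [rng.normal(0, 1, template.shape) for _ in range(3)]
        with pytest.raises(ValueError, match="rejected"):
            pm.correlation_average(members, reject_below=1.1)


class TestSymmetrize:
    def test_projection_idempotent(self, ring_topo):
        sym1 = pm.symmetrize(ring_topo.heights, 30)
        sym2 = pm.symmetrize(sym1, 30)
        assert np.abs(sym2 - sym1).max() < 0.05

    def test_spectral_power_only_at_multiples(self):
        topo, p = render_ring(24, phase_deg=3.0)
        sym = pm.symmetrize(topo.heights, 24)
        t = pm.Topograph(sym, topo.pixel_size)
        c = _center_by_twofold(t, (t.extent_nm[1] / 2, t.extent_nm[0] / 2),
                               20.0)
        r = p.crest_diameter / 2
        power = rotational_power_spectrum(
            polar_unwrap(t, c, (r - 1.5, r + 1.5), 8 * 24, 8))
        non_multiples = [power[k] for k in range(1, len(power)) if k % 24]
        assert max(non_multiples) / power[24] < 1e-3

    def test_crest_diameter_preserved(self, ring_topo):
        before = pm.measure_particle(ring_topo, None).crest_diameter
        sym = pm.symmetrize(ring_topo.heights, 30)
        after = pm.measure_particle(
            pm.Topograph(sym, ring_topo.pixel_size), None).crest_diameter
        assert after == pytest.approx(before, abs=0.25)  # 0.5 px


class TestCoordsToTopograph:
    def test_single_atom_peak_height(self):
        topo = pm.coords_to_topograph(np.array([[5.0, 5.0, 3.2]]),
                                      pixel_size=0.1, atom_radius=0.2)
        assert topo.heights.max() == pytest.approx(3.4, abs=1e-6)

    def test_rendered_ring_model_has_n_fold_spectrum(self, monomer):
        model = pm.build_ring(monomer, 30, 7.85)
        topo = pm.coords_to_topograph(model, pixel_size=0.25)
        rec = pm.measure_particle(topo, None)
        res = pm.particle_stoichiometry(topo, rec.center,
                                        rec.crest_diameter / 2)
        assert res.detected_n == 30

    def test_model_average_consistency(self, monomer):
        # The class average of noisy posed renders of a model correlates
        # strongly with the model's own pseudo-topograph.
        model = pm.build_ring(monomer, 24, 6.3)
        reference = pm.coords_to_topograph(model, pixel_size=0.5,
                                           probe_radius=0.3)
        rng = np.random.default_rng(4)
        members = [apply_transform(reference.heights, rng.uniform(0, 360),
                                   tuple(rng.uniform(-2, 2, 2)))
                   + rng.normal(0, 0.1, reference.shape) for _ in range(8)]
        ca = pm.correlation_average(members, stoichiometry=24)
        _, corr = pm.align_to_reference(ca.average, reference.heights)
        assert corr >= 0.9

    def test_empty_coordinates_rejected(self):
        with pytest.raises(ValueError):
            pm.coords_to_topograph([])
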