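"""Unit and property tests for the traction force microscopy module."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mechq import synthetic_data as sd
from mechq import tfm

from conftest import boussinesq_quadrature


def _gaussian_spot(shape, cx, cy, sigma=1.5, amplitude=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))


class TestDetectBeads:
    def test_blank_image_gives_no_beads(self):
        assert len(tfm.detect_beads(np.zeros((32, 32)), 3.0)) == 0

    def test_subpixel_center_recovered(self):
        img = _gaussian_spot((40, 40), 10.3, 20.7)
        beads = tfm.detect_beads(img, 3.5, intensity_percentile_cut=99)
        assert len(beads) == 1
        x, y = beads.positions[0]
        assert np.hypot(x - 10.3, y - 20.7) < 0.15

    def test_close_pair_suppressed_to_brighter(self):
        # two spots 0.4 bead-radii apart must collapse to one detection
        diameter = 6.0
        img = _gaussian_spot((40, 40), 20.0, 20.0, sigma=1.2, amplitude=100)
        img += _gaussian_spot((40, 40), 21.2, 20.0, sigma=1.2, amplitude=60)
        beads = tfm.detect_beads(img, diameter, intensity_percentile_cut=99)
        assert len(beads) == 1

    def test_rejects_bad_diameter(self):
        with pytest.raises(ValueError):
            tfm.detect_beads(np.zeros((8, 8)), 0.0)


class TestLinkBeads:
    def test_identity_matching(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 50, size=(20, 2))
        ref = tfm.BeadSet(pos)
        matches = tfm.link_beads(ref, tfm.BeadSet(pos.copy()), 5.0)
        assert len(matches) == 20
        assert np.allclose(matches[:, 2:], 0.0)

    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(5, 45, size=(15, 2))
        shifted = pos + [1.0, -0.5]
        matches = tfm.link_beads(tfm.BeadSet(pos), tfm.BeadSet(shifted), 3.0)
        assert len(matches) == 15
        assert np.allclose(matches[:, 2:], [1.0, -0.5])

    def test_no_partner_within_radius(self):
        ref = tfm.BeadSet(np.array([[0.0, 0.0]]))
        cur = tfm.BeadSet(np.array([[10.0, 10.0]]))
        assert len(tfm.link_beads(ref, cur, 3.0)) == 0

    def test_empty_inputs(self):
        assert len(tfm.link_beads(tfm.BeadSet(np.empty((0, 2))),
                                  tfm.BeadSet(np.empty((0, 2))), 1.0)) == 0

    def test_assignment_is_globally_optimal(self):
        # brute-force minimum over permutations for small sets
        rng = np.random.default_rng(2)
        for trial in range(5):
            n = 6
            ref = rng.uniform(0, 10, size=(n, 2))
            cur = ref[rng.permutation(n)] + rng.normal(0, 0.3, (n, 2))
            matches = tfm.link_beads(tfm.BeadSet(ref), tfm.BeadSet(cur), 50.0)
            cost = np.sum(matches[:, 2] ** 2 + matches[:, 3] ** 2)
            brute = min(
                float(np.sum((cur[list(p)] - ref) ** 2))
                for p in itertools.permutations(range(n))
            )
            assert cost == pytest.approx(brute, rel=1e-9)


class TestFilterOutliers:
    @staticmethod
    def _uniform_field(n=25, u=(1.0, 0.5)):
        g = np.mgrid[0:5, 0:5].reshape(2, -1).T * 10.0
        return np.column_stack([g, np.full(len(g), u[0]), np.full(len(g), u[1])])

    def test_single_large_outlier_removed(self):
        field = self._uniform_field()
        field[12, 2:] = [10.0, 5.0]  # 10x larger vector
        kept, warned = tfm.filter_outliers(field, neighborhood_k=8, threshold=2.0)
        assert not warned
        assert len(kept) == 24
        assert not any(np.allclose(row[2:], [10.0, 5.0]) for row in kept)

    def test_uniform_field_untouched(self):
        field = self._uniform_field()
        kept, _ = tfm.filter_outliers(field)
        assert len(kept) == len(field)

    def test_all_zero_field_floor_prevents_division(self):
        field = self._uniform_field(u=(0.0, 0.0))
        kept, _ = tfm.filter_outliers(field)
        assert len(kept) == len(field)

    def test_too_few_vectors_warns(self):
        field = self._uniform_field()[:4]
        with pytest.warns(UserWarning):
            kept, warned = tfm.filter_outliers(field, neighborhood_k=8)
        assert warned
        assert len(kept) == 4


class TestInterpolateField:
    def test_constant_field_reproduced(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 40, size=(50, 2))
        disp = np.column_stack([xy, np.full(50, 0.7), np.full(50, -0.2)])
        field = tfm.interpolate_field(disp, 2.0)
        assert np.allclose(field.ux, 0.7)
        assert np.allclose(field.uy, -0.2)

    def test_linear_field_reproduced_inside_hull(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 40, size=(80, 2))
        disp = np.column_stack([xy, 0.01 * xy[:, 0], np.zeros(80)])
        field = tfm.interpolate_field(disp, 2.0, origin_um=(0, 0), shape=(21, 21))
        gx = field.origin_um[0] + 2.0 * np.arange(21)
        expected = np.tile(0.01 * gx, (21, 1))
        inside = field.valid_mask
        assert np.allclose(field.ux[inside], expected[inside], atol=1e-6)

    def test_smooth_field_rms_below_5_percent(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 60, size=(400, 2))
        fx = lambda p: np.sin(p[:, 0] / 15) * np.cos(p[:, 1] / 20)
        fy = lambda p: np.cos(p[:, 0] / 18) * np.sin(p[:, 1] / 12)
        disp = np.column_stack([xy, fx(xy), fy(xy)])
        field = tfm.interpolate_field(disp, 2.0, origin_um=(0, 0), shape=(31, 31))
        gy, gx = np.mgrid[0:31, 0:31] * 2.0
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        tru_x = fx(pts).reshape(31, 31)
        tru_y = fy(pts).reshape(31, 31)
        m = field.valid_mask
        err = np.sqrt(np.mean((field.ux - tru_x)[m] ** 2 + (field.uy - tru_y)[m] ** 2))
        rms = np.sqrt(np.mean(tru_x[m] ** 2 + tru_y[m] ** 2))
        assert err < 0.05 * rms

    def test_collinear_points_rejected(self):
        xy = np.column_stack([np.arange(10.0), np.arange(10.0)])
        disp = np.column_stack([xy, np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="collinear"):
            tfm.interpolate_field(disp, 1.0)


class TestForwardModel:
    def test_zero_traction_zero_displacement(self, substrate):
        ux, uy = tfm.forward_displacement(
            np.zeros((16, 16)), np.zeros((16, 16)), 2.0, substrate
        )
        assert np.allclose(ux, 0) and np.allclose(uy, 0)

    def test_dipole_displacement_antisymmetry(self, substrate):
        # a balanced x-dipole centred mid-field: ux is antisymmetric
        # about the dipole midline (mirror column), by symmetry of the
        # Green's function
        n, d = 33, 2.0
        truth = sd.dipole_truth(
            (n, n), d, center_um=(32.0, 32.0), separation_um=10.0,
            patch_sigma_um=3.0, amplitude_Pa=100.0,
        )
        ux, _ = tfm.forward_displacement(truth.tx, truth.ty, d, substrate)
        mirrored = -ux[:, ::-1]
        scale = np.abs(ux).max()
        assert np.allclose(ux, mirrored, atol=0.02 * scale)

    def test_matches_real_space_quadrature(self, substrate):
        # independent oracle: direct midpoint quadrature of the
        # Boussinesq integral over the analytic patch field, compared
        # with the spectral model evaluated at off-node probe points
        rng = np.random.default_rng(10)
        n, d = 32, 2.0
        truth = sd.random_balanced_truth(
            (n, n), d, substrate.young_modulus_Pa, substrate.poisson_ratio,
            patch_sigma_cells=(2.0, 3.0), separation_cells=(4.0, 6.0),
            seed=11,
        )
        idx = rng.integers(8, 24, size=(12, 2))
        probes = np.array([(ix * d + 0.37 * d, iy * d + 0.61 * d) for iy, ix in idx])
        fux, fuy = tfm.forward_displacement_at(
            truth.tx, truth.ty, d, substrate, probes
        )
        qx, qy = boussinesq_quadrature(
            truth.tx, truth.ty, d, substrate, probes, subdiv=8,
            traction_fn=truth.traction_at,
        )
        num = np.linalg.norm(np.concatenate([fux - qx, fuy - qy]))
        den = np.linalg.norm(np.concatenate([qx, qy]))
        assert num / den < 0.02


class TestInvertFTTC:
    def test_zero_field_gives_zero_result(self, substrate):
        field = tfm.DisplacementField(2.0, np.zeros((16, 16)), np.zeros((16, 16)))
        res = tfm.invert_fttc(field, substrate, 0.0)
        assert np.allclose(res.tx, 0) and np.allclose(res.ty, 0)
        assert res.strain_energy_pJ == 0.0

    def test_round_trip_recovers_truth(self, substrate):
        truth = sd.random_balanced_truth(
            (64, 64), 2.0, substrate.young_modulus_Pa, substrate.poisson_ratio,
            seed=7,
        )
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        res = tfm.invert_fttc(
            tfm.DisplacementField(2.0, ux, uy), substrate, 1e-9
        )
        rel = np.linalg.norm(np.hypot(res.tx - truth.tx, res.ty - truth.ty))
        rel /= np.linalg.norm(np.hypot(truth.tx, truth.ty))
        assert rel < 0.05
        u_true = tfm.strain_energy(truth.tx, truth.ty, ux, uy, 2.0)
        assert res.strain_energy_pJ == pytest.approx(u_true, rel=0.05)

    def test_linearity_in_displacement(self, substrate):
        truth = sd.random_balanced_truth((32, 32), 2.0, seed=8)
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        r1 = tfm.invert_fttc(tfm.DisplacementField(2.0, ux, uy), substrate, 1e-6)
        r3 = tfm.invert_fttc(
            tfm.DisplacementField(2.0, 3 * ux, 3 * uy), substrate, 1e-6
        )
        assert np.allclose(r3.tx, 3 * r1.tx, atol=1e-8 * np.abs(r1.tx).max())
        assert np.allclose(r3.ty, 3 * r1.ty, atol=1e-8 * np.abs(r1.ty).max())

    def test_total_traction_non_increasing_in_lambda(self, substrate):
        truth = sd.random_balanced_truth((32, 32), 2.0, seed=9)
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        field = tfm.DisplacementField(2.0, ux, uy)
        totals = []
        for lam in (0.0, 1e-5, 1e-4, 1e-3, 1e-2):
            res = tfm.invert_fttc(field, substrate, lam)
            totals.append(res.magnitude.sum())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(totals, totals[1:]))

    def test_error_monotone_in_noise(self, substrate):
        truth = sd.random_balanced_truth((32, 32), 2.0, seed=12)
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        rng = np.random.default_rng(13)
        tn = np.linalg.norm(np.hypot(truth.tx, truth.ty))
        base_noise = rng.normal(0, 1, (2,) + ux.shape)
        errs = []
        for noise_sd in (0.0, 0.02, 0.1):
            field = tfm.DisplacementField(
                2.0, ux + noise_sd * base_noise[0], uy + noise_sd * base_noise[1]
            )
            res = tfm.invert_fttc(field, substrate, 1e-4)
            errs.append(
                np.linalg.norm(np.hypot(res.tx - truth.tx, res.ty - truth.ty)) / tn
            )
        assert errs[0] <= errs[1] <= errs[2]

    def test_uniform_energy_quadrature(self):
        # 100 Pa against 1 um over 100x100 um^2 -> 0.5 pJ
        t = np.full((50, 50), 100.0)
        u = np.full((50, 50), 1.0)
        assert tfm.strain_energy(t, np.zeros_like(t), u, np.zeros_like(u), 2.0) == (
            pytest.approx(0.5)
        )

    def test_rejects_invalid_parameters(self, substrate):
        field = tfm.DisplacementField(2.0, np.zeros((16, 16)), np.zeros((16, 16)))
        with pytest.raises(ValueError):
            tfm.invert_fttc(field, substrate, -1.0)
        with pytest.raises(ValueError):
            tfm.ElasticSubstrate(1000.0, 0.5)
        small = tfm.DisplacementField(2.0, np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            tfm.invert_fttc(small, substrate, 0.0)


class TestStrainEnergySeries:
    def test_zero_series(self, substrate):
        field = tfm.DisplacementField(2.0, np.zeros((16, 16)), np.zeros((16, 16)))
        series, peak = tfm.strain_energy_series([field], substrate, 0.0)
        assert series == [(0.0, 0.0)]
        assert peak == 0.0

    def test_peak_matches_constructed_maximum(self, substrate):
        truth = sd.random_balanced_truth((32, 32), 2.0, seed=14)
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        fields = [
            tfm.DisplacementField(2.0, c * ux, c * uy)
            for c in (0.0, 0.5, 1.0, 0.5, 0.0)
        ]
        series, peak = tfm.strain_energy_series(fields, substrate, 1e-9)
        u_true = tfm.strain_energy(truth.tx, truth.ty, ux, uy, 2.0)
        assert peak == pytest.approx(u_true, rel=0.05)
        assert series[2][1] == peak
        assert series[0][0] == 0.0 and series[1][0] == 30.0

    def test_identical_fields_identical_energies(self, substrate):
        truth = sd.random_balanced_truth((32, 32), 2.0, seed=15)
        ux, uy = tfm.forward_displacement(truth.tx, truth.ty, 2.0, substrate)
        field = tfm.DisplacementField(2.0, ux, uy)
        series, _ = tfm.strain_energy_series([field] * 3, substrate, 1e-6)
        energies = [u for _, u in series]
        assert np.ptp(energies) <= 1e-9 * max(energies)

    def test_empty_series_rejected(self, substrate):
        with pytest.raises(ValueError):
            tfm.strain_energy_series([], substrate)
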