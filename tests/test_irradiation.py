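import math

import numpy as np
import pytest

import casim
from casim.irradiation import KEV_J, _build_kernel


class TestFluence:
    def test_zero_dose(self):
        assert casim.fluence_from_dose(0.0, 99.0) == 0.0

    @pytest.mark.parametrize("let,expected", [
        (99.0, 6.313e6),      # high-LET Si-like beam, 1 Gy
        (0.22, 2.841e9),      # low-LET proton beam, 1 Gy
    ])
    def test_inverse_let_scaling(self, let, expected):
        assert casim.fluence_from_dose(1.0, let) == pytest.approx(
            expected, rel=1e-3)

    def test_roundtrip(self):
        phi = casim.fluence_from_dose(0.37, 50.0)
        assert casim.dose_from_fluence(phi, 50.0) == pytest.approx(0.37)

    def test_nonpositive_let_rejected(self):
        with pytest.raises(ValueError):
            casim.fluence_from_dose(1.0, 0.0)


class TestBeamRegistry:
    def test_all_entries_positive(self):
        for (_, e), (let, rng_cm) in casim.BEAM_REGISTRY.items():
            assert e > 0 and let > 0 and rng_cm > 0

    def test_ranges_far_exceed_nuclear_sizes(self):
        # justifies straight full-length chords: shortest range is 3 cm
        assert min(r for _, r in casim.BEAM_REGISTRY.values()) >= 2.8

    def test_unknown_beam(self):
        with pytest.raises(KeyError):
            casim.beam("Si", 171)


class TestMeanTraversals:
    def test_monotone_decreasing_in_let(self):
        nuc = casim.NucleusGeometry.sphere(4.0)
        lets = sorted(let for let, _ in casim.BEAM_REGISTRY.values())
        lams = [casim.mean_traversals(
            nuc, casim.IonBeam("X", 100, let), 1.0) for let in lets]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_proportional_to_projected_area(self):
        b = casim.beam("Si", 170)
        lam3 = casim.mean_traversals(casim.NucleusGeometry.sphere(3.0), b)
        lam6 = casim.mean_traversals(casim.NucleusGeometry.sphere(6.0), b)
        assert lam6 / lam3 == pytest.approx(4.0)

    def test_axis_dependence(self):
        nuc = casim.NucleusGeometry(10.22, 5.11, 3.00)
        bx = casim.IonBeam("Si", 170, 99.0, axis="x")
        bz = casim.IonBeam("Si", 170, 99.0, axis="z")
        ratio = casim.mean_traversals(nuc, bx) / casim.mean_traversals(nuc, bz)
        assert ratio == pytest.approx((5.11 * 3.00) / (10.22 * 5.11))


class TestTrackSampling:
    def test_zero_dose_zero_tracks(self):
        vol = casim.IrradiationVolume(15.0, 15.0, 15.0)
        tr = casim.sample_tracks(vol, casim.beam("Si", 170), 0.0, seed=1)
        assert tr.n_tracks == 0

    def test_poisson_moments_and_dispersion(self):
        # λ chosen near 4; 20000 histories; 3-SE bands
        vol = casim.IrradiationVolume(15.0, 15.0, 15.0)
        b = casim.IonBeam("T", 100, 99.0)
        dose = 4.0 / (casim.fluence_from_dose(1.0, 99.0) * 15.0 ** 2 * 1e-8)
        rng = np.random.default_rng(42)
        counts = np.array([
            casim.sample_tracks(vol, b, dose, rng).n_tracks
            for _ in range(20_000)])
        se = math.sqrt(4.0 / len(counts))
        assert abs(counts.mean() - 4.0) < 3 * se
        disp = counts.var(ddof=1) / counts.mean()
        assert abs(disp - 1.0) < 0.05

    def test_entry_points_cover_face(self):
        vol = casim.IrradiationVolume(15.0, 15.0, 15.0)
        tr = casim.sample_tracks(vol, casim.beam("H", 1000), 0.3, seed=7)
        assert tr.n_tracks > 500
        assert (np.abs(tr.entry_points_um) <= 7.5).all()
        # both halves of each lateral axis populated
        assert (tr.entry_points_um > 0).any(axis=0).all()
        assert (tr.entry_points_um < 0).any(axis=0).all()

    def test_volume_for_nucleus_encloses(self):
        nuc = casim.NucleusGeometry(10.22, 5.11, 3.00)
        vol = casim.IrradiationVolume.for_nucleus(nuc)
        assert vol.encloses(nuc)
        assert min(vol.side_x_um, vol.side_y_um, vol.side_z_um) >= 15.0


class TestDoseScoring:
    def _one_track(self, entry=(0.0, 0.0), beam=None, nucleus=None):
        b = beam or casim.beam("Si", 170)
        nuc = nucleus or casim.NucleusGeometry.sphere(3.0)
        vol = casim.IrradiationVolume.for_nucleus(nuc)
        tr = casim.TrackSample(b, vol, 0.5, 0.0, 0.0,
                               np.array([entry], dtype=float))
        return casim.score_dose_grid(tr, volume=vol), vol, b

    def test_zero_tracks_empty_grid(self):
        vol = casim.IrradiationVolume(15.0, 15.0, 15.0)
        tr = casim.sample_tracks(vol, casim.beam("Si", 170), 0.0, seed=1)
        grid = casim.score_dose_grid(tr, volume=vol)
        assert grid.mean_dose_gy == 0.0
        assert (grid.lateral_dose_gy == 0).all()

    @pytest.mark.parametrize("species,energy", [("Si", 170), ("H", 1000),
                                                ("Fe", 450)])
    def test_per_track_energy_equals_let_times_path(self, species, energy):
        grid, vol, b = self._one_track(beam=casim.beam(species, energy))
        expected = b.let_kev_um * KEV_J * vol.side("z")
        assert grid.total_energy_j == pytest.approx(expected, rel=1e-2)

    def test_energy_conserved_under_periodic_wrap(self):
        # a track at the very corner of the face wraps laterally
        center, _, _ = self._one_track((0.0, 0.0))
        corner, _, _ = self._one_track((7.49, 7.49))
        assert corner.total_energy_j == pytest.approx(
            center.total_energy_j, rel=1e-12)

    def test_expected_scored_dose_matches_prescription(self):
        """λ(D) × per-track dose = D: the dose-closure identity."""
        nuc = casim.NucleusGeometry.sphere(3.0)
        b = casim.beam("Si", 170)
        vol = casim.IrradiationVolume.for_nucleus(nuc)
        grid, _, _ = self._one_track()
        lam = casim.fluence_from_dose(0.5, b.let_kev_um) \
            * vol.face_area_um2("z") * 1e-8
        assert lam * grid.mean_dose_gy == pytest.approx(0.5, rel=5e-3)

    def test_ensemble_scored_dose(self):
        """Monte Carlo closure at 0.5 Gy within 3 SE of the track count."""
        nuc = casim.NucleusGeometry.sphere(3.0)
        b = casim.beam("Si", 170)
        vol = casim.IrradiationVolume.for_nucleus(nuc)
        rng = np.random.default_rng(3)
        doses = []
        for _ in range(400):
            tr = casim.sample_tracks(vol, b, 0.5, rng)
            doses.append(casim.score_dose_grid(tr, volume=vol).mean_dose_gy)
        doses = np.array(doses)
        se = doses.std(ddof=1) / math.sqrt(len(doses))
        assert abs(doses.mean() - 0.5) < 3 * se

    def test_core_voxel_exceeds_complexity_threshold(self):
        grid, _, _ = self._one_track()
        peak_ev = grid.lateral_dose_gy.max() * casim.EV_PER_GY_VOXEL
        assert peak_ev >= 500.0  # high-LET core voxels carry >500 eV per slab

    def test_kernel_fraction_below_one(self):
        m = casim.RadialDoseModel.for_beam(casim.beam("H", 1000))
        _, f = _build_kernel(m, 0.22, 2.0)
        assert 0 < f < 1
        assert m.cumulative_fraction(m.penumbra_radius_um) == pytest.approx(1.0)

    def test_radial_profile_integrates_to_let(self):
        b = casim.beam("Si", 170)
        m = casim.RadialDoseModel.for_beam(b)
        r = np.logspace(math.log10(m.core_radius_um / 30),
                        math.log10(m.penumbra_radius_um), 200_000)
        d = m.dose_gy(r, b.let_kev_um)
        rho = 1e-15  # kg/µm³
        integral = np.trapezoid(d * 2 * math.pi * r * rho, r)  # J/µm
        assert integral == pytest.approx(b.let_kev_um * KEV_J, rel=0.01)

    def test_dose_at_lattice_wraps_periodically(self):
        grid, vol, _ = self._one_track()
        n0, _ = grid.n_lateral
        pts = np.array([[5, 7, 0], [5 + n0, 7, 0], [5 - n0, 7, 0]])
        d = grid.dose_at_lattice(pts)
        assert d[0] == d[1] == d[2]

    def test_region_outside_volume_rejected(self):
        nuc = casim.NucleusGeometry.sphere(3.0)
        vol = casim.IrradiationVolume.for_nucleus(nuc)
        tr = casim.sample_tracks(vol, casim.beam("Si", 170), 0.1, seed=1)
        with pytest.raises(ValueError, match="region"):
            casim.score_dose_grid(tr, volume=vol,
                                  region_um=[[-20, -1, -1], [1, 1, 1]])

    def test_stochastic_mode_preserves_mean(self):
        b = casim.beam("Si", 170)
        vol = casim.IrradiationVolume(15.0, 15.0, 15.0)
        rng = np.random.default_rng(5)
        tr = casim.sample_tracks(vol, b, 0.5, rng)
        det = casim.score_dose_grid(tr, volume=vol)
        sto = casim.score_dose_grid(tr, volume=vol, stochastic=True, seed=9)
        # Poisson-count noise of the discretised depositions: the mean-dose
        # SE is q·sqrt(Σλ)/N for quantum q and per-voxel counts λ
        n_vox = det.lateral_dose_gy.size
        q_gy = 60.0 / casim.EV_PER_GY_VOXEL
        counts = det.mean_dose_gy * n_vox / q_gy
        se = q_gy * math.sqrt(counts) / n_vox
        assert abs(sto.mean_dose_gy - det.mean_dose_gy) < 4 * se
        sto2 = casim.score_dose_grid(tr, volume=vol, stochastic=True, seed=9)
        assert (sto.lateral_dose_gy == sto2.lateral_dose_gy).all()


def test_voxel_energy_conversion():
    # 1 Gy in an 8e-18 g water voxel is 4.99e-2 eV
    assert casim.EV_PER_GY_VOXEL == pytest.approx(4.993e-2, rel=1e-3)
    assert casim.COMPLEX_THRESHOLD_GY == pytest.approx(1.0014e4, rel=1e-3)
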