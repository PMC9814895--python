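"""Occupancy accumulation, pseudo-sites, thermodynamics, clustering, OC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrascore.grids import GridSpec, ScalarGrid
from hydrascore.hydration import (
    KB,
    N_SPHERE_BINS,
    _SPHERE_BIN_CENTERS,
    BulkReference,
    HydrationThermoGrids,
    WaterTrajectory,
    accumulate_occupancy,
    cluster_hydration_sites,
    detect_pseudo_sites,
    encode_hydration_channels,
    load_energy_table,
    load_water_trajectory,
    overlap_coefficient,
    site_thermodynamics,
    site_translational_entropy,
    thermo_grids,
)


def fixed_water_traj(position, n_frames, energy=-12.0):
    pos = np.asarray(position, float)
    return WaterTrajectory(
        frames=[pos[None, :].copy() for _ in range(n_frames)],
        energies=[np.array([energy]) for _ in range(n_frames)],
        water_ids=[np.array([0]) for _ in range(n_frames)],
    )


@pytest.fixture
def spec():
    return GridSpec((0.0, 0.0, 0.0), 8.0, 1.0)


class TestOccupancy:
    def test_fixed_oxygen_counting(self, spec):
        bulk = BulkReference(-10.0, 0.2)
        center = spec.center_of((3, 3, 3))
        occ = accumulate_occupancy(fixed_water_traj(center, 100), spec, bulk)
        assert occ.values[3, 3, 3] == pytest.approx(1 / 0.2)
        assert occ.values.sum() == pytest.approx(5.0)  # single voxel visited

    def test_count_conservation_exact(self, spec):
        rng = np.random.default_rng(0)
        frames = [spec.origin_corner + rng.uniform(0, 8, (7, 3))
                  for _ in range(50)]
        traj = WaterTrajectory(frames,
                               [np.full(7, -10.0)] * 50,
                               [np.arange(7)] * 50)
        bulk = BulkReference(-10.0, 0.05)
        occ = accumulate_occupancy(traj, spec, bulk)
        total_visits = occ.values.sum() * bulk.bulk_occupancy * 50
        assert total_visits == pytest.approx(50 * 7, abs=1e-9)

    def test_uniform_bulk_mean_ratio_near_one(self):
        spec = GridSpec((0.0, 0.0, 0.0), 10.0, 1.0)
        rng = np.random.default_rng(1)
        density = 0.2  # waters per A^3 -> 200 per frame in the box
        n_frames = 1000
        n_w = int(density * 1000)
        frames = [spec.origin_corner + rng.uniform(0, 10, (n_w, 3))
                  for _ in range(n_frames)]
        traj = WaterTrajectory(frames, [np.zeros(n_w)] * n_frames,
                               [np.arange(n_w)] * n_frames)
        occ = accumulate_occupancy(
            traj, spec, BulkReference(-10.0, density * spec.voxel_volume))
        # per-voxel binomial: mean ratio within 3 standard errors of 1
        se = np.sqrt((1 - 1e-3) / (n_frames * n_w * 1e-3)) / np.sqrt(1000)
        assert abs(occ.values.mean() - 1.0) < 3 * se

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            WaterTrajectory([], [], [])


class TestPseudoSites:
    def test_uniform_grid_no_sites(self, spec):
        occ = ScalarGrid(spec, np.ones(spec.shape))
        traj = fixed_water_traj((0, 0, 0), 1)
        assert detect_pseudo_sites(occ, traj, BulkReference(-10, 0.1)) == []

    def test_single_hot_voxel(self, spec):
        center = spec.center_of((2, 5, 4))
        traj = fixed_water_traj(center, 100)
        bulk = BulkReference(-10.0, 0.2)
        occ = accumulate_occupancy(traj, spec, bulk)
        sites = detect_pseudo_sites(occ, traj, bulk)
        assert len(sites) == 1
        assert sites[0].voxel_index == (2, 5, 4)
        assert sites[0].n_contributing == 100

    def test_ratio_exactly_two_is_not_a_site(self, spec):
        vals = np.ones(spec.shape)
        vals[1, 1, 1] = 2.0
        occ = ScalarGrid(spec, vals)
        traj = fixed_water_traj(spec.center_of((1, 1, 1)), 1)
        assert detect_pseudo_sites(occ, traj, BulkReference(-10, 0.1)) == []


class TestThermodynamics:
    def test_enthalpy_is_mean_minus_bulk(self, spec):
        center = spec.center_of((3, 3, 3))
        traj = fixed_water_traj(center, 50, energy=-12.0)
        bulk = BulkReference(-10.0, 0.2)
        occ = accumulate_occupancy(traj, spec, bulk)
        sites = site_thermodynamics(
            traj, detect_pseudo_sites(occ, traj, bulk), bulk)
        assert sites[0].dH == pytest.approx(-2.0)

    def test_uniform_subbins_zero_entropy(self):
        # one observation per sub-bin center: q is exactly uniform
        assert site_translational_entropy(_SPHERE_BIN_CENTERS) == pytest.approx(
            0.0, abs=1e-12)

    def test_point_mass_entropy(self):
        rel = np.zeros((40, 3)) + 0.01
        expected = 300.0 * KB * np.log(N_SPHERE_BINS)
        assert site_translational_entropy(rel) == pytest.approx(expected)

    def test_zero_contributor_site_rejected(self, spec):
        from hydrascore.hydration import PseudoHydrationSite

        site = PseudoHydrationSite((0, 0, 0), np.zeros(3), 3.0, 0)
        traj = fixed_water_traj((0, 0, 0), 1)
        with pytest.raises(ValueError, match="0, 0, 0"):
            site_thermodynamics(traj, [site], BulkReference(-10, 0.1))

    def test_thermo_grids_defined_only_on_sites(self, spec):
        center = spec.center_of((3, 3, 3))
        traj = fixed_water_traj(center, 50)
        bulk = BulkReference(-10.0, 0.2)
        tg = thermo_grids(traj, spec, bulk)
        assert tg.enthalpy.values[3, 3, 3] == pytest.approx(-2.0)
        mask = np.ones(spec.shape, bool)
        mask[3, 3, 3] = False
        assert not tg.enthalpy.values[mask].any()


class TestClustering:
    def _blob(self, spec, center_idx, height):
        centers = spec.voxel_centers()
        c = spec.center_of(center_idx)
        d2 = np.sum((centers - c) ** 2, axis=-1)
        return height * np.exp(-d2 / 2.0)

    def test_two_blobs_two_sites(self):
        spec = GridSpec((0.0, 0.0, 0.0), 12.0, 1.0)
        vals = self._blob(spec, (2, 6, 6), 8.0) + self._blob(spec, (9, 6, 6), 6.0)
        sites = cluster_hydration_sites(ScalarGrid(spec, vals))
        assert len(sites) == 2
        np.testing.assert_allclose(sites[0].center, spec.center_of((2, 6, 6)),
                                   atol=spec.spacing)
        np.testing.assert_allclose(sites[1].center, spec.center_of((9, 6, 6)),
                                   atol=spec.spacing)
        assert sites[0].peak_occupancy > sites[1].peak_occupancy

    def test_uniform_bulk_no_sites(self, spec):
        assert cluster_hydration_sites(ScalarGrid(spec, np.ones(spec.shape))) == []

    def test_single_blob_at_argmax(self):
        spec = GridSpec((0.0, 0.0, 0.0), 8.0, 1.0)
        vals = self._blob(spec, (4, 3, 5), 5.0)
        sites = cluster_hydration_sites(ScalarGrid(spec, vals))
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].center, spec.center_of((4, 3, 5)))

    def test_site_separation_at_least_two_angstrom(self):
        spec = GridSpec((0.0, 0.0, 0.0), 10.0, 0.5)
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, spec.shape)
        sites = cluster_hydration_sites(ScalarGrid(spec, vals))
        centers = np.array([s.center for s in sites])
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.0


class TestChannels:
    def _grids(self, spec, dh=None, ts=None):
        zeros = ScalarGrid.zeros(spec)
        return HydrationThermoGrids(
            occupancy=zeros,
            enthalpy=ScalarGrid(spec, dh) if dh is not None else zeros,
            entropy_term=ScalarGrid(spec, ts) if ts is not None else zeros,
        )

    def test_zero_enthalpy_gives_zero_channels(self, spec):
        ch = encode_hydration_channels(self._grids(spec), "thermo")
        assert ch.n_channels == 3
        assert not ch.data.any()

    def test_tanh_scaling_negative_enthalpy(self, spec):
        dh = np.full(spec.shape, -1.5)
        ch = encode_hydration_channels(self._grids(spec, dh=dh), "thermo",
                                       s_H=1.0)
        h_neg = ch.data[ch.names.index("dH_negative")]
        h_pos = ch.data[ch.names.index("dH_positive")]
        assert h_neg[0, 0, 0] == pytest.approx(np.tanh(1.5))
        assert not h_pos.any()

    def test_tanh_scaling_entropy(self, spec):
        ts = np.full(spec.shape, 0.8)
        ch = encode_hydration_channels(self._grids(spec, ts=ts), "thermo",
                                       s_S=1.0)
        assert ch.data[2][0, 0, 0] == pytest.approx(np.tanh(0.8))

    def test_monotone_in_enthalpy_magnitude(self, spec):
        vals = np.linspace(0, 10, np.prod(spec.shape)).reshape(spec.shape)
        ch = encode_hydration_channels(self._grids(spec, dh=-vals), "thermo")
        h_neg = ch.data[0].reshape(-1)
        assert np.all(np.diff(h_neg) >= 0)

    def test_nonfinite_rejected(self, spec):
        dh = np.zeros(spec.shape)
        dh[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            encode_hydration_channels(self._grids(spec, dh=dh), "thermo")


class TestOverlapCoefficient:
    def _grid(self, spec, flat):
        vals = np.zeros(spec.shape)
        vals.reshape(-1)[: len(flat)] = flat
        return ScalarGrid(spec, vals)

    def test_identical_grids(self, spec):
        g = self._grid(spec, np.arange(1, 10))
        assert overlap_coefficient(g, g) == pytest.approx(1.0)

    def test_disjoint_supports(self, spec):
        a = self._grid(spec, [1, 1, 0, 0])
        b = self._grid(spec, [0, 0, 1, 1])
        assert overlap_coefficient(a, b) == pytest.approx(0.0)

    def test_hand_example(self, spec):
        a = self._grid(spec, [1, 1, 0])
        b = self._grid(spec, [0, 1, 1])
        assert overlap_coefficient(a, b) == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_symmetric_scale_invariant_bounded(self, seed):
        spec = GridSpec((0, 0, 0), 3.0, 1.0)
        rng = np.random.default_rng(seed)
        a = ScalarGrid(spec, rng.uniform(0, 1, spec.shape))
        b = ScalarGrid(spec, rng.uniform(0, 1, spec.shape))
        oc = overlap_coefficient(a, b)
        assert 0.0 <= oc <= 1.0
        assert oc == pytest.approx(overlap_coefficient(b, a))
        scaled = ScalarGrid(spec, 7.3 * a.values)
        assert oc == pytest.approx(overlap_coefficient(scaled, b))

    def test_negative_values_rejected(self, spec):
        a = self._grid(spec, [1.0, -0.5])
        b = self._grid(spec, [1.0, 1.0])
        with pytest.raises(ValueError, match="magnitude"):
            overlap_coefficient(a, b)

    def test_zero_total_rejected(self, spec):
        a = ScalarGrid.zeros(spec)
        b = self._grid(spec, [1.0])
        with pytest.raises(ValueError, match="zero-total"):
            overlap_coefficient(a, b)


class TestTrajectoryIO:
    def _traj_text(self):
        frames = []
        for f in range(2):
            lines = ["MODEL     %d" % (f + 1)]
            for w in range(2):
                x = 1.0 + w + 0.1 * f
                lines.append(
                    f"HETATM{w + 1:>5} O    HOH A{w + 1:>4}    "
                    f"{x:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00           O"
                )
            lines.append("ENDMDL")
            frames.append("\n".join(lines))
        return "\n".join(frames) + "\n"

    def _energy_text(self, ww_halved=True):
        rows = [f"# ww_halved: {'true' if ww_halved else 'false'}"]
        for f in range(2):
            for w in range(2):
                rows.append(f"{f}\t{w + 1}\t{-10.0 - w}")
        return "\n".join(rows) + "\n"

    def test_multiframe_pdb_with_energies(self):
        traj = load_water_trajectory(self._traj_text(), self._energy_text())
        assert traj.n_frames == 2
        assert len(traj.frames[0]) == 2
        assert traj.energies[1][1] == pytest.approx(-11.0)

    def test_ww_halving_applied(self):
        ww = "# ww_halved: true\n" + "\n".join(
            f"{f}\t{w + 1}\t{-2.0}" for f in range(2) for w in range(2))
        traj = load_water_trajectory(
            self._traj_text(), self._energy_text(ww_halved=False), ww)
        # total -10 with full ww -2 counted once -> corrected -10 + 1 = -9
        assert traj.energies[0][0] == pytest.approx(-9.0)

    def test_missing_header_warns(self):
        text = "0\t1\t-10.0\n"
        with pytest.warns(UserWarning, match="ww_halved"):
            load_energy_table(text)
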