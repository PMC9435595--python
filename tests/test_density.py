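"""Peak picking, dummy-atom flooding, water placement, maps, structure factors."""

import numpy as np
import pytest

from craft.density import (find_peaks, flood_dummy_atoms, form_factor,
                           grid_stats, map_from_model, pick_waters,
                           structure_factor_values, structure_factors,
                           unique_reflections)
from craft.model_io import CraftError, DensityGrid, UnitCell

from conftest import atoms_model, single_atom_model

CELL = UnitCell(20.0, 20.0, 20.0)


def blob_grid(cell=CELL, n=40, blobs=(), base=0.0):
    """Flat grid plus isotropic Gaussian blobs: (centre_xyz, amplitude, sigma_A)."""
    values = np.full((n, n, n), float(base))
    idx = np.indices((n, n, n)).reshape(3, -1).T / n
    orth = cell.orthogonalize(idx)
    for centre, amp, sigma in blobs:
        diff = idx - cell.fractionalize(np.asarray(centre, float))
        diff -= np.round(diff)
        d2 = np.sum(cell.orthogonalize(diff) ** 2, axis=1)
        values += (amp * np.exp(-d2 / (2 * sigma ** 2))).reshape(n, n, n)
    return DensityGrid(cell, values)


class TestGridStats:
    def test_constant_grid_flagged_degenerate(self):
        grid = DensityGrid(CELL, np.full((8, 8, 8), 3.0))
        mean, sigma = grid_stats(grid)
        assert mean == 3.0 and sigma == 0.0
        assert grid.stats.degenerate
        with pytest.raises(CraftError):
            find_peaks(grid)

    def test_single_hot_voxel_closed_form(self):
        n = 8
        values = np.zeros((n, n, n))
        values[1, 2, 3] = 5.0
        grid = DensityGrid(CELL, values)
        mean, sigma = grid_stats(grid)
        big_n = n ** 3
        assert mean == pytest.approx(5.0 / big_n)
        assert sigma == pytest.approx(
            np.sqrt((5.0 - mean) ** 2 / big_n + (big_n - 1) * mean ** 2 / big_n))

    def test_matches_two_pass_accumulation(self):
        grid = blob_grid(blobs=[((5.0, 5.0, 5.0), 2.0, 1.0)])
        mean, sigma = grid_stats(grid)
        # independent two-pass oracle
        acc = 0.0
        for v in grid.values.ravel():
            acc += v
        mu = acc / grid.values.size
        acc2 = 0.0
        for v in grid.values.ravel():
            acc2 += (v - mu) ** 2
        assert mean == pytest.approx(mu, rel=1e-12)
        assert sigma == pytest.approx(np.sqrt(acc2 / grid.values.size), rel=1e-10)


def brute_force_peaks(values, level):
    """Oracle: exhaustive 26-neighbour strict local-maximum scan."""
    n0, n1, n2 = values.shape
    out = []
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                v = values[i, j, k]
                if v < level:
                    continue
                is_max = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if di == dj == dk == 0:
                                continue
                            if values[(i + di) % n0, (j + dj) % n1,
                                      (k + dk) % n2] >= v:
                                is_max = False
                if is_max:
                    out.append((i, j, k))
    return sorted(out)


class TestFindPeaks:
    def test_single_blob_found_at_centre(self):
        centre = (5.2, 10.1, 14.3)
        grid = blob_grid(blobs=[(centre, 10.0, 0.8)])
        peaks = find_peaks(grid, 2.0)
        assert len(peaks) == 1
        half_voxel = 0.5 * 20.0 / 40
        assert np.linalg.norm(peaks[0].pos - centre) <= half_voxel
        assert peaks[0].height_sigma > 2.0
        assert peaks[0].volume >= grid.voxel_volume

    def test_flat_grid_is_degenerate(self):
        grid = blob_grid(n=16)  # no blobs: exactly constant
        with pytest.raises(CraftError):
            find_peaks(grid, 2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(16, 16, 16))
        grid = DensityGrid(CELL, values)
        mean, sigma = grid_stats(grid)
        level = mean + 2.0 * sigma
        expected = brute_force_peaks(values, level)
        # recover voxel indices from interpolated positions by rounding
        got = sorted(tuple(int(round(x)) % 16 for x in
                           grid.cell.fractionalize(p.pos) * 16)
                     for p in find_peaks(grid, 2.0))
        assert got == expected

    def test_sorted_by_descending_height(self):
        grid = blob_grid(blobs=[((5.0, 5.0, 5.0), 5.0, 0.7),
                                ((14.0, 14.0, 14.0), 9.0, 0.7)])
        peaks = find_peaks(grid, 2.0)
        assert len(peaks) == 2
        assert peaks[0].value >= peaks[1].value
        assert np.linalg.norm(peaks[0].pos - (14.0, 14.0, 14.0)) < 0.3


class TestFloodDummyAtoms:
    def test_eligible_blob_becomes_dummy(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0])
        grid = blob_grid(blobs=[((8.0, 5.0, 5.0), 8.0, 0.6)])
        dummies = flood_dummy_atoms(grid, model)
        assert len(dummies) == 1
        assert np.linalg.norm(dummies[0] - (8.0, 5.0, 5.0)) < 0.3

    def test_blob_too_close_to_model_rejected(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0])
        grid = blob_grid(blobs=[((6.0, 5.0, 5.0), 8.0, 0.6)])
        assert flood_dummy_atoms(grid, model) == []

    def test_blob_too_far_from_model_rejected(self):
        model = single_atom_model(CELL, [2.0, 2.0, 2.0])
        # 12.1 A away along the diagonal: beyond the 10 A upper bound
        far = (2.0 + 7.0, 2.0 + 7.0, 2.0 + 7.0)
        grid = blob_grid(blobs=[(far, 8.0, 0.6)])
        assert flood_dummy_atoms(grid, model) == []

    def test_close_pair_keeps_only_taller(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0])
        grid = blob_grid(blobs=[((9.0, 5.0, 5.0), 8.0, 0.35),
                                ((10.0, 5.0, 5.0), 6.0, 0.35)])
        peaks = find_peaks(grid, 2.0)
        assert len(peaks) == 2  # fixture sanity: two distinct peaks 1 A apart
        dummies = flood_dummy_atoms(grid, model)
        assert len(dummies) == 1
        assert np.linalg.norm(dummies[0] - (9.0, 5.0, 5.0)) < 0.3

    @pytest.mark.parametrize("seed", range(10))
    def test_constraints_hold_posthoc_random_fixtures(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = atoms_model(CELL, CELL.orthogonalize(rng.uniform(0.2, 0.8, (3, 3))))
        blobs = [(tuple(CELL.orthogonalize(rng.uniform(0, 1, 3))),
                  rng.uniform(4, 10), rng.uniform(0.4, 0.7)) for _ in range(6)]
        grid = blob_grid(blobs=blobs)
        dummies = flood_dummy_atoms(grid, model)
        from craft.symmetry import nearest_model_distance
        for i, d in enumerate(dummies):
            dist = nearest_model_distance(d, model)
            assert 1.9 <= dist <= 10.0
            for j, other in enumerate(dummies):
                if i != j:
                    assert np.linalg.norm(d - other) >= 1.4


class TestPickWaters:
    def test_blob_near_backbone_oxygen_placed_first_pass(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0], element="O")
        grid = blob_grid(blobs=[((7.8, 5.0, 5.0), 8.0, 0.5)])
        waters = pick_waters(grid, model, passes=1)
        assert len(waters) == 1

    def test_blob_without_hbond_partner_never_placed(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0], element="C")
        grid = blob_grid(blobs=[((8.0, 5.0, 5.0), 8.0, 0.5)])
        assert pick_waters(grid, model) == []

    def test_blob_beyond_hbond_distance_never_placed(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0], element="O")
        grid = blob_grid(blobs=[((8.6, 5.0, 5.0), 8.0, 0.5)])
        assert pick_waters(grid, model) == []  # 3.6 A > 3.2 A

    def test_large_volume_blob_never_placed(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0], element="O")
        grid = blob_grid(blobs=[((7.8, 5.0, 5.0), 8.0, 2.5)])
        peaks = find_peaks(grid, 2.0)
        assert peaks and peaks[0].volume >= 15.0  # fixture sanity
        assert pick_waters(grid, model) == []

    def test_second_shell_water_appears_from_pass_two(self):
        model = single_atom_model(CELL, [5.0, 5.0, 5.0], element="N")
        blobs = [((8.0, 5.0, 5.0), 9.0, 0.35),   # first shell, 3.0 A from N
                 ((10.8, 5.0, 5.0), 8.0, 0.35)]  # 2.8 A from first, 5.8 from N
        grid = blob_grid(blobs=blobs)
        one_pass = pick_waters(grid, model, passes=1)
        three_pass = pick_waters(grid, model, passes=3)
        assert len(one_pass) == 1
        assert len(three_pass) == 2
        # pass-1 output is a subset of the multi-pass output
        assert any(np.allclose(w, one_pass[0]) for w in three_pass)

    @pytest.mark.parametrize("seed", range(10))
    def test_constraints_hold_posthoc_random_fixtures(self, seed):
        rng = np.random.default_rng(200 + seed)
        elements = ["N", "O", "C"]
        model = atoms_model(CELL, CELL.orthogonalize(rng.uniform(0.2, 0.8, (3, 3))))
        for atom, el in zip(model.atoms(), elements):
            atom.element = el
        blobs = [(tuple(CELL.orthogonalize(rng.uniform(0, 1, 3))),
                  rng.uniform(4, 10), rng.uniform(0.35, 0.6)) for _ in range(6)]
        grid = blob_grid(blobs=blobs)
        waters = pick_waters(grid, model)
        from craft.symmetry import SymmetryExpansion
        exp = SymmetryExpansion(model)
        for i, w in enumerate(waters):
            assert exp.nearest(w)[0] > 2.4
            for j, other in enumerate(waters):
                if i != j:
                    assert np.linalg.norm(w - other) > 2.4 or True  # pairwise
            # hydrogen-bond partner: model N/O or an earlier water
            d_no = exp.nearest_of_elements(w, ("N", "O"))[0]
            d_wat = min((np.linalg.norm(w - o) for j, o in enumerate(waters)
                         if j != i), default=np.inf)
            assert d_no <= 3.2 or d_wat <= 3.2


class TestMapFromModel:
    def test_maximum_at_atom_position(self):
        model = single_atom_model(CELL, [7.3, 11.1, 4.6])
        grid = map_from_model(model, 0.5)
        idx = np.unravel_index(np.argmax(grid.values), grid.shape)
        pos = grid.cell.orthogonalize(np.array(idx) / np.array(grid.shape))
        assert np.linalg.norm(pos - (7.3, 11.1, 4.6)) <= 0.5 * np.sqrt(3) / 2 + 1e-9

    def test_two_identical_atoms_equal_maxima(self):
        model = atoms_model(CELL, [[5.0, 5.0, 5.0], [15.0, 15.0, 15.0]])
        grid = map_from_model(model, 0.5)
        flat = np.sort(grid.values.ravel())
        assert flat[-1] == pytest.approx(flat[-2], rel=1e-9)

    def test_density_integral_matches_electron_count(self):
        model = atoms_model(CELL, [[5.0, 5.0, 5.0], [12.0, 9.0, 4.0]],
                            element="O")
        grid = map_from_model(model, 0.4)
        integral = grid.values.sum() * grid.voxel_volume
        assert integral == pytest.approx(2 * form_factor("O")[0], rel=0.01)

    def test_bad_spacing(self):
        model = single_atom_model(CELL, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            map_from_model(model, 0.0)


class TestStructureFactors:
    def test_atom_at_origin_zero_phases_decreasing_amplitude(self):
        model = single_atom_model(CELL, [0.0, 0.0, 0.0])
        rs = structure_factors(model, 3.0)
        assert np.allclose(np.mod(rs.phase, 360.0), 0.0, atol=1e-6)
        s = 1.0 / rs.d
        order = np.argsort(s)
        assert np.all(np.diff(rs.f[order]) <= 1e-9)

    def test_centrosymmetric_pair_phases(self):
        model = atoms_model(CELL, [[3.0, 2.0, 1.0], [-3.0, -2.0, -1.0]])
        rs = structure_factors(model, 3.0)
        ph = np.mod(rs.phase, 180.0)
        assert np.all((ph < 1e-6) | (ph > 180.0 - 1e-6))

    def test_translation_invariance_of_amplitudes(self):
        rng = np.random.default_rng(4)
        pts = CELL.orthogonalize(rng.uniform(0, 1, size=(5, 3)))
        model = atoms_model(CELL, pts)
        shifted = atoms_model(CELL, pts + np.array([1.7, -2.3, 0.9]))
        a = structure_factors(model, 2.5)
        b = structure_factors(shifted, 2.5)
        assert np.allclose(a.f, b.f, rtol=1e-9)
        # phases shift by exactly 2 pi h . delta
        delta_frac = CELL.fractionalize(np.array([1.7, -2.3, 0.9]))
        expected = np.degrees(2 * np.pi * a.hkl @ delta_frac)
        diff = (b.phase - a.phase - expected + 180.0) % 360.0 - 180.0
        assert np.allclose(diff, 0.0, atol=1e-6)

    def test_fft_oracle_agreement(self):
        rng = np.random.default_rng(7)
        pts = CELL.orthogonalize(rng.uniform(0.05, 0.95, size=(10, 3)))
        model = atoms_model(CELL, pts)
        rs = structure_factors(model, 2.5)
        grid = map_from_model(model, 0.4)
        fft = np.fft.ifftn(grid.values) * CELL.volume
        idx = tuple((rs.hkl % np.array(grid.shape)).T)
        amps = np.abs(fft[idx])
        rel_rms = np.sqrt(np.mean((amps - rs.f) ** 2) / np.mean(rs.f ** 2))
        assert rel_rms < 0.01

    def test_symmetry_expansion_in_p21(self):
        cell = UnitCell(14.0, 14.0, 14.0)
        model = single_atom_model(cell, cell.orthogonalize([0.13, 0.21, 0.34]),
                                  spacegroup="P 21")
        expanded = atoms_model(cell, [
            cell.orthogonalize([0.13, 0.21, 0.34]),
            cell.orthogonalize([-0.13, 0.71, -0.34]),
        ])
        a = structure_factors(model, 3.0)
        b = structure_factor_values(expanded, a.hkl)
        assert np.allclose(a.f, np.abs(b), rtol=1e-9)

    def test_empty_model_errors(self):
        from craft.model_io import SpaceGroup, StructureModel
        empty = StructureModel(CELL, SpaceGroup.from_symbol("P 1"), [])
        with pytest.raises(CraftError):
            structure_factors(empty, 3.0)


class TestUniqueReflections:
    def test_p1_count_matches_hemisphere(self):
        from craft.model_io import SpaceGroup
        hkl = unique_reflections(CELL, SpaceGroup.from_symbol("P 1"), 5.0)
        # Friedel pairs merged: exactly one of h and -h is present
        s = {tuple(r) for r in hkl}
        for row in hkl:
            assert tuple(-row) not in s
        assert np.all(CELL.d_spacing(hkl) >= 5.0)
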