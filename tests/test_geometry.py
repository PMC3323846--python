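"""Scanner geometry, LOR indexing and the symmetry group."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blobpet.geometry import (ScannerSpec, SymmetryTransform, all_transforms,
                              apply_transform, build_crystal_table,
                              build_symmetry_lut, lor_count, lor_index,
                              lor_unindex, transform_blobs, transform_crystals,
                              transform_lors)


class TestCrystalTable:
    def test_default_spec_reproduces_published_counts(self, default_spec):
        table = build_crystal_table(default_spec)
        assert len(table) == 1152
        assert lor_count(default_spec) == 662976

    def test_degenerate_single_crystal(self):
        spec = ScannerSpec(n_modules=3, n_layers=1, crystals_tangential=1,
                           crystals_axial=1, crystal_size_mm=((1.0, 1.0, 1.0),),
                           layer_face_radius_mm=(5.0,), axial_pitch_mm=1.0,
                           tangential_pitch_mm=1.0)
        table = build_crystal_table(spec)
        assert len(table) == 3
        # module 0 sits at angle 0: +x axis
        np.testing.assert_allclose(table.positions[0], [5.0, 0.0, 0.0],
                                   atol=1e-12)

    def test_rotation_by_one_module_permutes_positions(self, default_spec):
        """Brute force: rotating every position by 2*pi/18 reproduces the
        position set (nearest-neighbour match below 1e-9 mm)."""
        table = build_crystal_table(default_spec)
        ang = 2 * np.pi / default_spec.n_modules
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = table.positions @ R.T
        d2 = ((rotated[:, None, :] - table.positions[None, :, :]) ** 2
              ).sum(-1)
        nearest = d2.min(axis=1)
        match = d2.argmin(axis=1)
        assert nearest.max() < 1e-18
        assert len(np.unique(match)) == len(table)   # a permutation

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScannerSpec(n_modules=2)
        with pytest.raises(ValueError):
            ScannerSpec(crystals_axial=0)
        with pytest.raises(ValueError):
            ScannerSpec(crystal_size_mm=((2.0, 2.0, -6.0), (2.0, 2.0, 8.0)))

    def test_tuple_flat_bijection(self, mini_spec):
        cid = np.arange(mini_spec.n_crystals)
        assert np.array_equal(
            mini_spec.crystal_id(*mini_spec.crystal_tuple(cid)), cid)

    def test_csv_export(self, mini_spec, tmp_path):
        table = build_crystal_table(mini_spec)
        out = tmp_path / "crystals.csv"
        table.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("id,module,layer")
        assert len(lines) == len(table) + 1


class TestLORIndex:
    @pytest.mark.parametrize("pair,expected", [
        ((0, 1), 0), ((1, 0), 0), ((1150, 1151), 662975)])
    def test_known_values(self, pair, expected):
        assert lor_index(*pair) == expected

    def test_rejects_equal_crystals(self):
        with pytest.raises(ValueError):
            lor_index(3, 3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 1151), st.integers(0, 1151))
    def test_round_trip(self, a, b):
        if a == b:
            return
        d = lor_index(a, b)
        assert 0 <= d < 662976
        assert lor_unindex(d) == (min(a, b), max(a, b))

    def test_lor_count_small(self):
        # brute-force pair enumeration for 4 crystals
        spec = ScannerSpec(n_modules=4, n_layers=1, crystals_tangential=1,
                           crystals_axial=1, crystal_size_mm=((1, 1, 1),),
                           layer_face_radius_mm=(5.0,), axial_pitch_mm=1.0,
                           tangential_pitch_mm=1.0)
        pairs = {(a, b) for a in range(4) for b in range(4) if a < b}
        assert lor_count(spec) == len(pairs) == 6


class TestSymmetryGroup:
    def test_group_order(self, default_spec, mini_spec):
        assert default_spec.n_transforms == 72
        assert len(all_transforms(default_spec)) == 72
        assert mini_spec.n_transforms == 24

    def test_identity_and_involutions(self, mini_spec):
        ident = SymmetryTransform.from_id(0, 6)
        assert ident.id == 0
        d = 17
        assert transform_lors(ident, mini_spec, d) == d
        mz = SymmetryTransform(rot=0, mirror_t=False, mirror_z=True,
                               n_modules=6)
        cid = np.arange(mini_spec.n_crystals)
        assert np.array_equal(
            transform_crystals(mz, mini_spec, transform_crystals(
                mz, mini_spec, cid)), cid)

    def test_closure_and_action_homomorphism(self, default_spec):
        """Exhaustive 72 x 72: the composition law lands inside the group
        and matches composition of the crystal permutations."""
        ts = all_transforms(default_spec)
        ids = {t.id for t in ts}
        cid = np.arange(default_spec.n_crystals)
        perms = {t.id: transform_crystals(t, default_spec, cid) for t in ts}
        for t1 in ts:
            for t2 in ts:
                t12 = t1.compose(t2)
                assert t12.id in ids
                assert np.array_equal(perms[t1.id][perms[t2.id]],
                                      perms[t12.id])

    def test_inverses(self, default_spec):
        cid = np.arange(default_spec.n_crystals)
        for t in all_transforms(default_spec):
            assert t.compose(t.inverse()).id == 0
            assert np.array_equal(
                transform_crystals(t.inverse(), default_spec,
                                   transform_crystals(t, default_spec, cid)),
                cid)

    def test_out_of_range_rejected(self, mini_spec, mini_grid):
        t = SymmetryTransform.from_id(5, 6)
        with pytest.raises(ValueError):
            transform_crystals(t, mini_spec, mini_spec.n_crystals)
        with pytest.raises(ValueError):
            transform_lors(t, mini_spec, lor_count(mini_spec))
        with pytest.raises(ValueError):
            transform_blobs(t, mini_grid, mini_grid.n_blobs)
        with pytest.raises(ValueError):
            apply_transform(t, mini_spec, 0, kind="nonsense")

    def test_lor_orbits_partition(self, mini_spec):
        """Brute-force orbit enumeration: orbits are disjoint, no larger
        than the group, and cover the LOR set exactly."""
        ts = all_transforms(mini_spec)
        n = lor_count(mini_spec)
        seen = set()
        total = 0
        for d in range(n):
            if d in seen:
                continue
            orbit = {transform_lors(t, mini_spec, d) for t in ts}
            assert len(orbit) <= mini_spec.n_transforms
            assert not (orbit & seen)
            seen |= orbit
            total += len(orbit)
        assert total == n


class TestSymmetryLUT:
    def test_lut_reconstructs_every_element(self, mini_spec, mini_grid,
                                            mini_lut):
        for b in range(mini_grid.n_blobs):
            t = SymmetryTransform.from_id(int(mini_lut.blob_tf[b]), 6)
            assert transform_blobs(t, mini_grid,
                                   int(mini_lut.blob_canon[b])) == b
        for d in range(lor_count(mini_spec)):
            t = SymmetryTransform.from_id(int(mini_lut.lor_tf[d]), 6)
            assert transform_lors(t, mini_spec,
                                  int(mini_lut.lor_canon[d])) == d

    def test_canonical_is_unique_orbit_member(self, mini_spec, mini_grid,
                                              mini_lut):
        ts = all_transforms(mini_spec)
        canon = set(np.unique(mini_lut.blob_canon))
        for b in canon:
            orbit = {int(transform_blobs(t, mini_grid, b)) for t in ts}
            assert len(orbit & canon) == 1

    def test_wedge_blob_is_own_canonical_with_identity(self, mini_lut):
        for b in mini_lut.wedge_blobs:
            assert mini_lut.blob_canon[b] == b
            assert mini_lut.lor_perms[mini_lut.blob_tf[b]][0] >= 0  # valid id
            assert mini_lut.blob_tf[b] == 0

    def test_wedge_unfolds_without_gaps_or_duplicates(self, mini_spec,
                                                     mini_grid, mini_lut):
        ts = all_transforms(mini_spec)
        produced = []
        for b in mini_lut.wedge_blobs:
            produced.extend({int(transform_blobs(t, mini_grid, b))
                             for t in ts})
        assert sorted(produced) == list(range(mini_grid.n_blobs))

    def test_incommensurate_grid_rejected(self, mini_spec):
        from blobpet.blobgrid import BlobParams, build_polar_grid
        bad = build_polar_grid(2, 10, 2, 3.0, params=BlobParams(delta=3.0))
        with pytest.raises(ValueError, match="incommensurate|divisible"):
            build_symmetry_lut(mini_spec, bad)
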