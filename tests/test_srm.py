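"""System response matrix: builders, folding, transpose, validation."""

import numpy as np
import pytest

from blobpet.blobgrid import BlobParams, build_polar_grid
from blobpet.geometry import (all_transforms, build_crystal_table,
                              build_symmetry_lut, lor_count, lor_unindex,
                              transform_blobs, transform_lors)
from blobpet.srm import (analytic_srm_wedge, kb_footprint, mc_srm_wedge,
                         transpose_srm, unfold_full_matrix, unfold_lookup,
                         validate_srm)


class TestAnalyticProjector:
    def test_fold_unfold_equals_brute_force(self, mini_srm, mini_srm_full,
                                            mini_lut):
        """The wedge-folded SRM unfolded over the full symmetry group equals
        an SRM built with no symmetry use, elementwise to 1e-12 relative."""
        U = unfold_full_matrix(mini_srm, mini_lut).toarray()
        F = mini_srm_full.matrix.toarray()
        sig = np.abs(F) > 1e-9
        assert np.all(np.abs(U - F)[sig] / np.abs(F)[sig] < 1e-12)
        assert np.all(np.abs(U - F)[~sig] < 1e-12)

    def test_symmetry_equivariance_exact(self, mini_spec, mini_grid,
                                         mini_srm, mini_lut):
        """p_{T(d),T(b)} == p_{d,b} for sampled elements and transforms."""
        rng = np.random.default_rng(3)
        ds = rng.integers(0, lor_count(mini_spec), 20)
        bs = rng.integers(0, mini_grid.n_blobs, 20)
        for t in all_transforms(mini_spec)[::5]:
            for d, b in zip(ds, bs):
                td = transform_lors(t, mini_spec, int(d))
                tb = int(transform_blobs(t, mini_grid, int(b)))
                a = unfold_lookup(mini_srm, mini_lut, int(d), int(b))
                bb = unfold_lookup(mini_srm, mini_lut, td, tb)
                assert bb == pytest.approx(a, rel=1e-12, abs=1e-15)

    def test_distant_blob_has_no_element(self, mini_spec, mini_grid,
                                         mini_srm, mini_lut):
        """A blob farther than its radius from every chord of a LOR stores
        nothing (compact support)."""
        table = build_crystal_table(mini_spec)
        a = mini_grid.params.a
        found = 0
        for d in range(lor_count(mini_spec)):
            c1, c2 = lor_unindex(d)
            p1, p2 = table.positions[c1], table.positions[c2]
            u = (p2 - p1) / np.linalg.norm(p2 - p1)
            v = mini_grid.centres - p1
            dist = np.linalg.norm(v - (v @ u)[:, None] * u, axis=1)
            far = np.nonzero(dist > a + 3.0)[0]   # margin for face extent
            for b in far[:3]:
                assert unfold_lookup(mini_srm, mini_lut, d, int(b)) == 0.0
                found += 1
            if found > 30:
                break
        assert found > 0

    def test_single_ray_matches_direct_footprint(self, mini_spec, mini_grid,
                                                 mini_lut):
        """n_rays=1 uses the face-centre chord only: p equals the blob
        footprint at the chord distance, recomputed here from scratch."""
        srm1 = analytic_srm_wedge(mini_spec, mini_grid, mini_lut, n_rays=1,
                                  floor=0.0)
        table = build_crystal_table(mini_spec)
        rng = np.random.default_rng(11)
        for d in rng.integers(0, lor_count(mini_spec), 30):
            c1, c2 = lor_unindex(int(d))
            p1, p2 = table.positions[c1], table.positions[c2]
            u = (p2 - p1) / np.linalg.norm(p2 - p1)
            for b in rng.integers(0, mini_grid.n_blobs, 5):
                v = mini_grid.centres[b] - p1
                s = np.linalg.norm(v - (v @ u) * u)
                expected = (kb_footprint(s, mini_grid.params)
                            if s < mini_grid.params.a else 0.0)
                got = unfold_lookup(srm1, mini_lut, int(d), int(b))
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-13)

    def test_deterministic_rebuild_bit_identical(self, mini_spec, mini_grid,
                                                 mini_lut, mini_srm):
        again = analytic_srm_wedge(mini_spec, mini_grid, mini_lut, n_rays=4,
                                   floor=0.0)
        assert np.array_equal(again.values, mini_srm.values)
        assert np.array_equal(again.col_idx, mini_srm.col_idx)
        assert np.array_equal(again.row_ptr, mini_srm.row_ptr)

    def test_floor_drops_small_entries(self, mini_spec, mini_grid, mini_lut):
        floored = analytic_srm_wedge(mini_spec, mini_grid, mini_lut,
                                     n_rays=4, floor=1e-3)
        assert floored.nnz > 0
        assert floored.values.min() >= 1e-3

    def test_empty_overlap_reported(self, mini_spec):
        tiny = build_polar_grid(1, 12, 1, 1e-6,
                                params=BlobParams(delta=1e-6), n_modules=6)
        lut = build_symmetry_lut(mini_spec, tiny)
        with pytest.raises(ValueError, match="empty"):
            # blobs of ~2e-6 mm radius: no chord passes within support
            analytic_srm_wedge(mini_spec, tiny, lut, n_rays=1, floor=0.5)

    def test_candidate_entry_accounting(self, mini_spec, mini_grid,
                                        mini_srm, mini_lut):
        assert mini_srm.n_rows == lor_count(mini_spec)
        assert mini_srm.n_cols == mini_lut.n_wedge
        full = lor_count(mini_spec) * mini_grid.n_blobs
        assert mini_srm.n_rows * mini_grid.n_blobs == full


class TestTranspose:
    def test_involution_and_nnz(self, mini_srm):
        t = transpose_srm(mini_srm)
        assert t.ordering == "blob"
        assert t.nnz == mini_srm.nnz
        tt = transpose_srm(t)
        assert tt.ordering == "lor"
        assert (tt.matrix != mini_srm.matrix).nnz == 0

    def test_elementwise_spot_check(self, mini_srm, rng):
        t = transpose_srm(mini_srm)
        dense = mini_srm.matrix.toarray()
        rows = rng.integers(0, mini_srm.n_rows, 1000)
        cols = rng.integers(0, mini_srm.n_cols, 1000)
        for r, c in zip(rows, cols):
            assert t.matrix[c, r] == dense[r, c]


class TestUnfoldLookup:
    def test_canonical_blob_direct_read(self, mini_srm, mini_lut):
        dense = mini_srm.matrix.toarray()
        for b in mini_lut.wedge_blobs:
            col = mini_lut.wedge_col[b]
            for d in (0, 7, 100):
                assert unfold_lookup(mini_srm, mini_lut, d, int(b)) == \
                    dense[d, col]

    def test_out_of_range_rejected(self, mini_srm, mini_lut, mini_spec,
                                   mini_grid):
        with pytest.raises(ValueError):
            unfold_lookup(mini_srm, mini_lut, lor_count(mini_spec), 0)
        with pytest.raises(ValueError):
            unfold_lookup(mini_srm, mini_lut, 0, mini_grid.n_blobs)


class TestMonteCarlo:
    def test_seed_mandatory(self, mini_spec, mini_grid, mini_lut):
        with pytest.raises(ValueError, match="seed"):
            mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=10,
                         seed=None)

    def test_zero_events_empty(self, mini_spec, mini_grid, mini_lut):
        srm = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=0, seed=1)
        assert srm.nnz == 0

    def test_same_seed_reproducible(self, mini_spec, mini_grid, mini_lut):
        a = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=2000,
                         seed=42)
        b = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=2000,
                         seed=42)
        assert (a.matrix != b.matrix).nnz == 0

    def test_statistical_self_consistency(self, mini_spec, mini_grid,
                                          mini_lut):
        """Two independent MC realisations agree within 5 combined binomial
        standard errors on every element with appreciable probability."""
        n = 100000
        a = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=n, seed=11)
        b = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=n, seed=12)
        A = a.matrix.toarray()
        B = b.matrix.toarray()
        p = (A + B) / 2.0
        mask = p > 3e-4
        assert mask.any()
        se = np.sqrt(2.0 * p * (1 - p) / n)
        assert np.all(np.abs(A - B)[mask] < 5 * se[mask])

    def test_correlates_with_analytic_per_lor_orbit(self, mini_spec,
                                                    mini_grid, mini_lut,
                                                    mini_srm):
        """The MC estimator carries a per-LOR geometric acceptance that the
        analytic footprint projector deliberately absorbs into sensitivity;
        within one LOR symmetry orbit that factor is constant, so the two
        builders should be strongly proportional there."""
        mc = mc_srm_wedge(mini_spec, mini_grid, mini_lut, n_events=100000,
                          seed=3)
        M = mc.matrix.toarray()
        A = mini_srm.matrix.toarray()
        orbit = mini_lut.lor_canon
        ok_rows = np.nonzero(M.max(axis=1) > 3e-4)[0]
        assert len(ok_rows) > 0
        for canon in np.unique(orbit[ok_rows]):
            rows = np.nonzero(orbit == canon)[0]
            m = M[rows].ravel()
            a = A[rows].ravel()
            sel = (m > 0) | (a > 1e-6)
            if sel.sum() < 4 or a[sel].std() == 0:
                continue
            r = np.corrcoef(m[sel], a[sel])[0, 1]
            assert r > 0.9


class TestValidate:
    def test_valid_srm_clean_report(self, mini_srm):
        report = validate_srm(mini_srm)
        assert report["failures"] == []
        assert report["nnz"] == len(mini_srm.values)

    def test_injected_negative_reported(self, mini_srm):
        bad = mini_srm.matrix.copy()
        bad.data = bad.data.copy()
        bad.data[0] = -1.0
        from blobpet.srm import SparseSRM
        report = validate_srm(SparseSRM(matrix=bad, ordering="lor",
                                        wedge_folded=True))
        assert report["failures"] == ["negative values present"]
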