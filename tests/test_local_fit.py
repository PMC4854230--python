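"""SMOC scoring, per-residue profiles, Z-scores and flagging."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexfit import (DensityGrid, GridIndexSet, ResidueSegment,
                     compare_profiles, flag_poor_segments, segment_voxels,
                     simulate_density, smoc_profile, smoc_segment,
                     smoc_zscores)
from flexfit.core_model import AtomRecord, ModelStructure
from flexfit.local_fit import SMOCProfile, ZScoreProfile, _window_indices
from flexfit.synthetic_fixtures import FixtureSpec, make_fixture, perturb

RES = 3.0


def _point_structure(pos=(5.0, 5.0, 5.0)):
    return ModelStructure([AtomRecord(1, "CA", "C", "", "ALA", "A", 1, "",
                                      np.array(pos, dtype=float))])


def _brute_force_smoc(em, model, indices):
    num = den_a = den_b = 0.0
    for k, j, i in indices:
        a = em.values[k, j, i]
        b = model.values[k, j, i]
        num += a * b
        den_a += a * a
        den_b += b * b
    return num / np.sqrt(den_a * den_b)


class TestSegmentVoxels:
    def test_radius_below_spacing_gives_one_voxel(self):
        grid = DensityGrid(np.ones((11, 11, 11)), 1.0)
        st_ = _point_structure((5.0, 5.0, 5.0))
        seg = ResidueSegment("A", [1])
        vox = segment_voxels(grid, st_, seg, radius=0.99)
        assert len(vox) == 1
        np.testing.assert_array_equal(vox.indices[0], [5, 5, 5])

    def test_face_neighbors_brute_force(self):
        """radius = 1.01 * spacing on a cubic grid: center + 6 face
        neighbors, confirmed by a full-grid distance scan."""
        grid = DensityGrid(np.ones((11, 11, 11)), 1.0)
        st_ = _point_structure((5.0, 5.0, 5.0))
        vox = segment_voxels(grid, st_, ResidueSegment("A", [1]),
                             radius=1.01)
        assert len(vox) == 7
        brute = {(k, j, i)
                 for k in range(11) for j in range(11) for i in range(11)
                 if (i - 5) ** 2 + (j - 5) ** 2 + (k - 5) ** 2 <= 1.01 ** 2}
        assert {tuple(v) for v in vox.indices} == brute

    def test_overlapping_spheres_union(self):
        grid = DensityGrid(np.ones((11, 11, 11)), 1.0)
        atoms = [AtomRecord(1, "CA", "C", "", "ALA", "A", 1, "",
                            np.array([5.0, 5, 5])),
                 AtomRecord(2, "CA", "C", "", "ALA", "A", 2, "",
                            np.array([5.5, 5, 5]))]
        st2 = ModelStructure(atoms)
        both = segment_voxels(grid, st2, ResidueSegment("A", [1, 2]),
                              radius=1.0)
        one = segment_voxels(grid, st2, ResidueSegment("A", [1]), radius=1.0)
        other = segment_voxels(grid, st2, ResidueSegment("A", [2]),
                               radius=1.0)
        union = {tuple(v) for v in one.indices} | \
                {tuple(v) for v in other.indices}
        assert {tuple(v) for v in both.indices} == union

    def test_outside_grid_error(self):
        grid = DensityGrid(np.ones((4, 4, 4)), 1.0)
        st_ = _point_structure((50.0, 50.0, 50.0))
        with pytest.raises(ValueError, match="no voxels"):
            segment_voxels(grid, st_, ResidueSegment("A", [1]), radius=2.0)


class TestSMOCSegment:
    def test_hand_toy_values(self):
        """2-voxel mask with hand-set values matches the direct sum."""
        em = DensityGrid(np.zeros((2, 2, 2)), 1.0)
        mo = DensityGrid(np.zeros((2, 2, 2)), 1.0)
        em.values[0, 0, 0] = 1.0
        em.values[0, 0, 1] = 0.0
        mo.values[0, 0, 0] = 1.0
        mo.values[0, 0, 1] = 1.0
        vox = GridIndexSet(np.array([[0, 0, 0], [0, 0, 1]]))
        # direct: num=1, den=sqrt(1*2)
        assert smoc_segment(em, mo, vox) == pytest.approx(1 / np.sqrt(2))

    def test_matches_brute_force_oracle(self, rng):
        em = DensityGrid(rng.random((16, 16, 16)), 1.0)
        mo = DensityGrid(rng.random((16, 16, 16)), 1.0)
        idx = rng.integers(0, 16, size=(40, 3))
        idx = np.unique(idx, axis=0)
        vox = GridIndexSet(idx)
        assert smoc_segment(em, mo, vox) == pytest.approx(
            _brute_force_smoc(em, mo, idx), abs=1e-12)

    def test_scale_invariant_offset_sensitive(self, hlh, hlh_map):
        """SMOC is unchanged by positive scaling of the map but changed by
        an additive offset (contrast with mean-subtracted CCC)."""
        _, structure, _ = hlh
        mo = simulate_density(structure, RES, grid=hlh_map)
        seg = ResidueSegment.from_range("A", 3, 8)
        vox = segment_voxels(hlh_map, structure, seg)
        base = smoc_segment(hlh_map, mo, vox)
        scaled = hlh_map.copy_geometry(2.0 * hlh_map.values)
        assert smoc_segment(scaled, mo, vox) == pytest.approx(base,
                                                              abs=1e-12)
        offset = hlh_map.copy_geometry(hlh_map.values + 1.0)
        assert smoc_segment(offset, mo, vox) != pytest.approx(base,
                                                              abs=1e-6)

    def test_flat_density_error(self):
        em = DensityGrid(np.zeros((4, 4, 4)), 1.0)
        mo = DensityGrid(np.ones((4, 4, 4)), 1.0)
        vox = GridIndexSet(np.array([[0, 0, 0]]))
        with pytest.raises(ValueError, match="flat"):
            smoc_segment(em, mo, vox)


class TestSMOCProfile:
    def test_self_fit_is_one_everywhere(self, hlh, hlh_map):
        _, structure, ann = hlh
        prof = smoc_profile(hlh_map, structure, ann, RES)
        assert np.all(np.abs(prof.scores() - 1.0) < 1e-6)

    def test_displaced_loop_scores_below_all_sses(self, hlh, hlh_map):
        spec, structure, ann = hlh
        lo, hi = spec.loop_range()
        moved = perturb(structure, "loop_displace", 5.0, seed=3,
                        loop=(lo, hi))
        prof = smoc_profile(hlh_map, moved, ann, RES)
        loop_scores = [prof.per_residue[("A", r)] for r in range(lo, hi + 1)]
        sse_scores = [prof.per_residue[("A", r)]
                      for (c, r) in ann.sse_residues()]
        assert max(loop_scores) < min(sse_scores)

    def test_profile_totality_short_loop(self):
        """7-residue loop flanked by SSEs, window 9: windows extend over
        flank residues and every residue still gets exactly one score."""
        spec = FixtureSpec(kind="helix_loop_helix", helix_len=8, loop_len=7)
        structure, ann = make_fixture(spec)
        em = simulate_density(structure, RES, 1.0)
        prof = smoc_profile(em, structure, ann, RES, window=9)
        assert set(prof.per_residue) == {("A", r)
                                         for r in range(1, 8 + 7 + 8 + 1)}

    def test_window_indices_rules(self):
        # long run: window stays inside the run, shifted inward
        assert _window_indices(10, 8, 25, 40, 9) == list(range(8, 17))
        assert _window_indices(24, 8, 25, 40, 9) == list(range(17, 26))
        # short run: window extends into flanks symmetrically
        assert _window_indices(12, 10, 14, 40, 9) == list(range(8, 17))
        # chain terminus: shrunk
        assert _window_indices(1, 0, 4, 5, 9) == list(range(0, 5))


class TestZScores:
    def test_worked_example(self):
        """Profile (0.8, 0.8, 0.8, 0.8, 0.4): mu=0.72, sigma=0.16,
        Z = (+0.5, +0.5, +0.5, +0.5, -2.0)."""
        prof = SMOCProfile({("A", i): v for i, v in
                            enumerate([0.8, 0.8, 0.8, 0.8, 0.4], start=1)})
        z = smoc_zscores(prof)
        assert z.mu == pytest.approx(0.72)
        assert z.sigma == pytest.approx(0.16)
        expected = [0.5, 0.5, 0.5, 0.5, -2.0]
        np.testing.assert_allclose(
            [z.per_residue[("A", i)] for i in range(1, 6)], expected,
            atol=1e-12)

    def test_constant_profile_warns_zero(self):
        prof = SMOCProfile({("A", i): 0.9 for i in range(1, 6)})
        with pytest.warns(UserWarning, match="constant"):
            z = smoc_zscores(prof)
        assert all(v == 0.0 for v in z.per_residue.values())

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3,
                    max_size=60))
    def test_normalization_identity(self, values):
        """Whenever sigma > 0, mean(Z) = 0 and SD(Z) = 1."""
        prof = SMOCProfile({("A", i): v for i, v in enumerate(values)})
        if np.std(values) < 1e-12:
            return
        z = smoc_zscores(prof)
        arr = np.array(list(z.per_residue.values()))
        assert abs(arr.mean()) < 1e-9
        assert abs(arr.std() - 1.0) < 1e-9


class TestFlagging:
    def _zprof(self, zvals):
        return ZScoreProfile({("A", i): v
                              for i, v in enumerate(zvals, start=1)},
                             0.0, 1.0)

    def test_no_flags_when_all_above(self, hlh):
        _, _, ann = hlh
        z = self._zprof([0.2] * 30)
        assert flag_poor_segments(z, ann) == []

    def test_known_poor_runs_recovered(self, hlh):
        """Z dips over two disjoint runs of a 214-residue chain reproduce
        exactly those segment bounds."""
        from flexfit import SSEAnnotation
        z = {("A", i): 0.3 for i in range(1, 215)}
        for r in range(74, 81):
            z[("A", r)] = -1.5
        for r in range(185, 194):
            z[("A", r)] = -1.8
        flags = flag_poor_segments(ZScoreProfile(z, 0.0, 1.0),
                                   SSEAnnotation([]))
        bounds = [(f.res_seqs[0], f.res_seqs[-1]) for f in flags]
        assert bounds == [(74, 80), (185, 193)]

    def test_short_run_dropped(self, hlh):
        _, _, ann = hlh
        zvals = [0.2] * 30
        zvals[14] = -2.0
        assert flag_poor_segments(self._zprof(zvals), ann) == []
        zvals[15] = zvals[16] = -2.0
        flags = flag_poor_segments(self._zprof(zvals), ann)
        assert [(f.res_seqs[0], f.res_seqs[-1]) for f in flags] == [(15, 17)]

    def test_threshold_must_be_negative(self, hlh):
        _, _, ann = hlh
        with pytest.raises(ValueError):
            flag_poor_segments(self._zprof([0.0] * 5), ann, threshold=0.5)


class TestCompareProfiles:
    def test_identity(self):
        prof = SMOCProfile({("A", i): 0.5 + 0.01 * i for i in range(10)})
        df, summary = compare_profiles(prof, prof)
        assert (df["delta"] == 0).all()
        assert summary["fraction_improved"] == 0.0

    def test_uniform_shift(self):
        a = SMOCProfile({("A", i): 0.5 for i in range(10)})
        b = SMOCProfile({("A", i): 0.6 for i in range(10)})
        df, summary = compare_profiles(a, b)
        np.testing.assert_allclose(df["delta"], 0.1)
        assert summary["fraction_improved"] == 1.0
        assert summary["mean_delta"] == pytest.approx(0.1)

    def test_residue_mismatch_error(self):
        a = SMOCProfile({("A", 1): 0.5})
        b = SMOCProfile({("A", 2): 0.5})
        with pytest.raises(ValueError, match="differ"):
            compare_profiles(a, b)
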