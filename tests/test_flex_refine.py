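"""Restraints, objective, annealing engine and loop-ensemble refinement."""
import numpy as np
import pytest

from flexfit import (AnnealConfig, FixtureSpec, ResidueSegment, anneal,
                     build_restraints, freeze_interface, hierarchical_refine,
                     make_fixture, objective, perturb, refine_loop_ensemble,
                     rmsd, simulate_density)
from flexfit.core_model import (AtomRecord, ModelStructure, ResidueRange,
                                RigidBodyScheme)
from flexfit.flex_refine import (_density_term, _dihedral_values_grads,
                                 load_covalent_params)
from flexfit.density_ops import SIGMA_PER_RESOLUTION, _atom_weights
from flexfit.rigid_bodies import cluster_sses, scheme_for_level

RES = 3.0

FAST = AnnealConfig(steps_per_leg=30, cycles=2, seed=7, noise_scale=0.02)


def _two_free_carbons(distance):
    atoms = [AtomRecord(1, "C", "C", "", "UNK", "A", 1, "",
                        np.array([0.0, 0, 0])),
             AtomRecord(2, "C", "C", "", "UNK", "A", 2, "",
                        np.array([distance, 0, 0]))]
    return ModelStructure(atoms)


class TestRestraints:
    def test_input_structure_anchored_at_zero(self, hinge):
        """Bond/angle/improper means are taken from the input, so its own
        energy in those terms is exactly zero."""
        _, st, _ = hinge
        restraints = build_restraints(st)
        _, comps = restraints.energy(st.coords())
        assert comps["bonds"] == 0.0
        assert comps["angles"] == 0.0
        assert comps["impropers"] == 0.0

    @pytest.mark.parametrize("distance,expected", [(2.9, 100.0), (3.6, 0.0)])
    def test_nonbonded_lower_bound_hand_values(self, distance, expected):
        """Two free carbons (r_vdW 1.7): E = 400*(3.4-d)^2 below the bound,
        zero above it (one-sided), under the E = k*delta^2 convention."""
        params = load_covalent_params()
        params["vdw_scale"] = 1.0
        st = _two_free_carbons(distance)
        restraints = build_restraints(st, params)
        _, comps = restraints.energy(st.coords())
        assert comps["nonbonded"] == pytest.approx(expected, abs=1e-9)

    def test_gradient_matches_numerical(self, rng):
        spec = FixtureSpec(kind="helix_loop_helix", helix_len=6, loop_len=4)
        st, _ = make_fixture(spec)
        restraints = build_restraints(st)
        coords = st.coords() + rng.normal(0, 0.05, st.coords().shape)
        grad = restraints.gradient(coords)
        h = 1e-6
        for i in range(0, len(coords), 11):
            for k in range(3):
                cp = coords.copy()
                cp[i, k] += h
                cm = coords.copy()
                cm[i, k] -= h
                num = (restraints.energy(cp)[0]
                       - restraints.energy(cm)[0]) / (2 * h)
                assert grad[i, k] == pytest.approx(num, rel=1e-3, abs=1e-4)

    def test_dihedral_gradient_random_configs(self, rng):
        idx = np.array([[0, 1, 2, 3]])
        for _ in range(5):
            coords = rng.normal(0, 2, (4, 3))
            _, gs = _dihedral_values_grads(coords, idx)
            for a in range(4):
                for k in range(3):
                    h = 1e-7
                    cp = coords.copy()
                    cp[a, k] += h
                    cm = coords.copy()
                    cm[a, k] -= h
                    num = (_dihedral_values_grads(cp, idx, False)[0][0]
                           - _dihedral_values_grads(cm, idx, False)[0][0]
                           ) / (2 * h)
                    assert gs[a][0, k] == pytest.approx(num, abs=1e-5)

    def test_unknown_atom_topology_error(self):
        atoms = [AtomRecord(1, "CA", "C", "", "ALA", "A", 1, "",
                            np.array([0.0, 0, 0])),
                 AtomRecord(2, "XX", "C", "", "ALA", "A", 1, "",
                            np.array([9.0, 9, 9]))]  # unbondable
        with pytest.raises(ValueError, match="no covalent neighbor"):
            build_restraints(ModelStructure(atoms))


class TestObjective:
    def test_ground_truth_near_zero(self, hlh, hlh_map):
        _, st, _ = hlh
        restraints = build_restraints(st)
        total, comps = objective(st, hlh_map, restraints, w_em=1.0,
                                 resolution=RES)
        assert comps["density"] == pytest.approx(0.0, abs=1e-9)
        assert comps["bonds"] == comps["angles"] == comps["impropers"] == 0.0

    def test_rigid_motion_raises_density_only(self, hlh, hlh_map):
        """A rigid 2 Å shift increases the density term while the internal
        stereochemical terms stay exactly zero."""
        _, st, _ = hlh
        restraints = build_restraints(st)
        moved = st.with_coords(st.coords() + np.array([2.0, 0.0, 0.0]))
        _, comps = objective(moved, hlh_map, restraints, w_em=1.0,
                             resolution=RES)
        assert comps["density"] > 0.01
        for term in ("bonds", "angles", "impropers", "nonbonded",
                     "ramachandran"):
            assert comps[term] == pytest.approx(0.0, abs=1e-9)

    def test_bond_compression_hand_value(self, hlh, hlh_map):
        """Compressing one bond by 0.1 Å adds k_bond * 0.01 to the bond
        term (E = k*delta^2)."""
        _, st, _ = hlh
        restraints = build_restraints(st)
        # pick a bond whose second atom has no other bonds (a carbonyl O),
        # so moving it perturbs exactly one bond term
        degree = np.zeros(len(st), dtype=int)
        for a, b in restraints.bond_idx:
            degree[a] += 1
            degree[b] += 1
        which = next(n for n, (a, b) in enumerate(restraints.bond_idx)
                     if degree[b] == 1)
        i, j = restraints.bond_idx[which]
        k_bond = restraints.bond_k[which]
        coords = st.coords()
        direction = coords[j] - coords[i]
        direction /= np.linalg.norm(direction)
        coords2 = coords.copy()
        coords2[j] -= 0.1 * direction
        _, comps = restraints.energy(coords2)
        assert comps["bonds"] == pytest.approx(k_bond * 0.01, rel=1e-6)


class TestAnneal:
    def _single_body(self, n_res):
        return RigidBodyScheme([[ResidueRange("A", 1, n_res)]],
                               level="custom")

    def test_stability_at_optimum(self, helix20):
        """Starting at the ground truth, one cycle leaves the model in
        place and the CCC essentially unchanged."""
        _, st, _ = helix20
        em = simulate_density(st, RES, 1.0)
        scheme = self._single_body(20)
        restraints = build_restraints(st)
        cfg = AnnealConfig(steps_per_leg=30, cycles=1, seed=3,
                           noise_scale=0.02)
        refined, trace = anneal(st, em, scheme, restraints, cfg, RES)
        assert rmsd(st, refined) < 0.2
        assert abs(trace.ccc_values()[-1] - 1.0) < 0.005

    def test_translated_helix_recovery_with_cap(self, helix20):
        """2 Å translation recovered to < 0.5 Å Calpha RMSD; the logged
        per-step per-axis displacement never exceeds the 0.39 Å cap."""
        _, gt, _ = helix20
        em = simulate_density(gt, RES, 1.0)
        start = perturb(gt, "translate", 2.0, seed=1)
        restraints = build_restraints(start)
        cfg = AnnealConfig(steps_per_leg=40, cycles=2, max_step=0.39,
                           seed=7, noise_scale=0.02)
        refined, trace = anneal(start, em, self._single_body(20),
                                restraints, cfg, RES)
        assert rmsd(gt, refined) < 0.5
        assert max(trace.max_steps()) <= 0.39 + 1e-9

    def test_seeded_determinism(self, helix20):
        _, gt, _ = helix20
        em = simulate_density(gt, RES, 1.0)
        start = perturb(gt, "translate", 1.0, seed=2)
        restraints = build_restraints(start)
        a, _ = anneal(start, em, self._single_body(20), restraints, FAST,
                      RES)
        b, _ = anneal(start, em, self._single_body(20), restraints, FAST,
                      RES)
        assert np.array_equal(a.coords(), b.coords())

    def test_rigid_body_distances_conserved(self, hlh, hlh_map):
        """Rigid-body stages conserve intra-body interatomic distances."""
        _, gt, ann = hlh
        start = perturb(gt, "translate", 1.5, seed=4)
        scheme = scheme_for_level(ann, None, "sse")
        restraints = build_restraints(start)
        refined, _ = anneal(start, hlh_map, scheme, restraints, FAST, RES)
        for idx in scheme.body_atom_indices(start):
            a = start.coords()[idx]
            b = refined.coords()[idx]
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            assert np.abs(da - db).max() < 1e-6

    def test_no_density_no_drift(self, hlh, hlh_map):
        """With w_em = 0 the anchored restraints alone hold the ground
        truth in place."""
        _, gt, _ = hlh
        restraints = build_restraints(gt)
        cfg = AnnealConfig(steps_per_leg=30, cycles=1, seed=5, w_em=0.0,
                           noise_scale=0.02, max_step=0.1)
        refined, _ = anneal(gt, hlh_map,
                            RigidBodyScheme([], level="all_atom"),
                            restraints, cfg, RES)
        assert rmsd(gt, refined, selection="all_atom") < 0.25


class TestHierarchical:
    def test_zero_iterations_identity(self, hinge, hinge_map):
        _, st, ann = hinge
        cfg = AnnealConfig(cycles=0)
        out, trace = hierarchical_refine(st, hinge_map, ann, None, cfg, RES)
        assert out is st
        assert trace.ccc_by_cycle == []

    def test_single_domain_starts_at_sse_level(self, hlh, hlh_map):
        """One cluster only: the large-rigid-body stage is skipped and the
        run begins by constraining SSEs as rigid bodies."""
        _, st, ann = hlh
        clusters = cluster_sses(st, ann)
        assert len(clusters.bodies) == 1
        out, trace = hierarchical_refine(st, hlh_map, ann, clusters, FAST,
                                         RES)
        stages = [s for s, _, _ in trace.ccc_by_cycle]
        assert "ribfind_clusters" not in stages
        assert stages[0] == "sse"

    def test_hinge_recovery_improves_all_stages(self, hinge, hinge_map):
        spec, gt, ann = hinge
        start = perturb(gt, "hinge", 15.0, seed=2,
                        linker=spec.linker_range())
        initial = rmsd(gt, start)
        clusters = cluster_sses(start, ann)
        cfg = AnnealConfig(steps_per_leg=40, cycles=2, seed=11,
                           noise_scale=0.02)
        refined, trace = hierarchical_refine(start, hinge_map, ann,
                                             clusters, cfg, RES)
        final = rmsd(gt, refined)
        assert final < 1.0
        assert final < initial
        means = [p.scores().mean() for p in trace.smoc_profiles]
        # non-decreasing at the resolution that is meaningful once the fit
        # has converged (stage means differ only by ~1e-5 jitter there)
        assert all(b >= a - 1e-4 for a, b in zip(means, means[1:]))
        caps = {"ribfind_clusters": 0.39, "sse": 0.15, "all_atom": 0.1}
        for stage, cap in caps.items():
            logged = trace.max_steps(stage)
            assert logged and max(logged) <= cap + 1e-9


class TestFreezeInterface:
    def test_empty_list_is_identity(self, hlh):
        _, _, ann = hlh
        scheme = scheme_for_level(ann, None, "sse")
        assert freeze_interface(scheme, []) is scheme

    def test_overlap_with_existing_body_rejected(self, hlh):
        _, _, ann = hlh
        scheme = scheme_for_level(ann, None, "sse")
        with pytest.raises(ValueError, match="overlap"):
            freeze_interface(scheme, [ResidueSegment.from_range("A", 10,
                                                                14)])

    def test_frozen_segment_rigid_through_anneal(self, hlh, hlh_map):
        """A frozen interface loop shows zero internal-distance drift over
        a full all-atom anneal."""
        spec, gt, ann = hlh
        start = perturb(gt, "translate", 1.5, seed=9)
        lo, hi = spec.loop_range()
        seg = ResidueSegment.from_range("A", lo, hi, "interface")
        scheme = freeze_interface(scheme_for_level(ann, None, "all_atom"),
                                  [seg])
        restraints = build_restraints(start)
        cfg = AnnealConfig(steps_per_leg=40, cycles=2, max_step=0.1, seed=5,
                           noise_scale=0.02)
        refined, _ = anneal(start, hlh_map, scheme, restraints, cfg, RES)
        idx = seg.atom_indices(start)
        a = start.coords()[idx]
        b = refined.coords()[idx]
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        assert np.abs(da - db).max() <= 1e-9


class TestLoopEnsemble:
    def test_zero_amplitude_returns_input(self, hlh, hlh_map):
        spec, gt, _ = hlh
        lo, hi = spec.loop_range()
        loop = ResidueSegment.from_range("A", lo, hi)
        out, table = refine_loop_ensemble(gt, hlh_map, loop, n=1,
                                          amplitude=0.0, resolution=RES)
        assert np.array_equal(out.coords(), gt.coords())
        assert len(table) == 1

    def test_ground_truth_ranks_first_among_decoys(self, hlh, hlh_map):
        """Ground-truth loop seeded into an ensemble of >= 2 Å decoys is
        ranked first by SMOC and substituted."""
        spec, gt, _ = hlh
        lo, hi = spec.loop_range()
        loop = ResidueSegment.from_range("A", lo, hi)
        bad = perturb(gt, "loop_displace", 4.0, seed=5, loop=(lo, hi))
        candidates = [gt.coords()]
        rng = np.random.default_rng(1)
        k = 0
        while len(candidates) < 20:
            k += 1
            try:
                decoy = perturb(gt, "loop_displace",
                                float(rng.uniform(2.5, 4.5)),
                                seed=100 + k, loop=(lo, hi))
            except ValueError:
                continue
            if rmsd(gt, decoy, selection=loop) >= 2.0:
                candidates.append(decoy.coords())
        out, table = refine_loop_ensemble(bad, hlh_map, loop,
                                          candidates=candidates,
                                          resolution=RES)
        assert table.iloc[0]["candidate"] == "candidate_0"
        assert np.allclose(out.coords(), gt.coords())

    def test_sampled_ensemble_improves_loop_windows(self, hlh, hlh_map):
        """After selection from a sampled ensemble, every loop-window SMOC
        strictly increases relative to the mis-built start."""
        from flexfit import smoc_profile
        spec, gt, ann = hlh
        lo, hi = spec.loop_range()
        loop = ResidueSegment.from_range("A", lo, hi)
        bad = perturb(gt, "loop_displace", 4.0, seed=5, loop=(lo, hi))
        cfg = AnnealConfig(seed=4)
        out, table = refine_loop_ensemble(bad, hlh_map, loop, n=40,
                                          amplitude=25.0, config=cfg,
                                          resolution=RES)
        before = smoc_profile(hlh_map, bad, ann, RES)
        after = smoc_profile(hlh_map, out, ann, RES)
        for r in range(lo, hi + 1):
            assert after.per_residue[("A", r)] > before.per_residue[("A", r)]

    def test_loop_must_be_interior(self, hlh, hlh_map):
        with pytest.raises(ValueError, match="interior"):
            refine_loop_ensemble(hlh[1], hlh_map,
                                 ResidueSegment.from_range("A", 1, 5),
                                 n=1, resolution=RES)


def test_density_gradient_matches_numerical(hlh, hlh_map, rng):
    _, st, _ = hlh
    weights = _atom_weights(st)
    sigma = SIGMA_PER_RESOLUTION * RES
    coords = st.coords() + rng.normal(0, 0.3, st.coords().shape)
    _, grad, _ = _density_term(coords, weights, hlh_map, sigma, 1.0)
    h = 1e-5
    for i in (0, 40, 149):
        for k in range(3):
            cp = coords.copy()
            cp[i, k] += h
            cm = coords.copy()
            cm[i, k] -= h
            vp = _density_term(cp, weights, hlh_map, sigma, 1.0, False)[0]
            vm = _density_term(cm, weights, hlh_map, sigma, 1.0, False)[0]
            assert grad[i, k] == pytest.approx((vp - vm) / (2 * h),
                                               rel=1e-4, abs=1e-10)
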