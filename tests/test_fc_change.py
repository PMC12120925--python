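import numpy as np
import pytest

from disuse._utils import child_seed
from disuse.fc_change import (
    FCMap,
    _cohens_d,
    permutation_cluster_correct,
    phase_effect_size,
    seed_fc_map,
)
from disuse.simulate import SimParams, make_space, make_truth, simulate_run

from conftest import make_run


def fc(r, sid, phase):
    return FCMap(r=np.asarray(r, dtype=float), session_id=sid, phase=phase)


class TestSeedFCMap:
    def test_single_voxel_seed_is_plain_correlation_map(self, rng):
        run = make_run(rng.standard_normal((12, 80)))
        m = seed_fc_map(run, [3])
        expect = np.array([np.corrcoef(run.data[3], run.data[i])[0, 1]
                           for i in range(12)])
        np.testing.assert_allclose(m.r, expect, atol=1e-12)

    def test_duplicated_seed_voxel_signal_equals_single(self, rng):
        data = rng.standard_normal((10, 60))
        data[1] = data[0]
        run = make_run(data)
        m2 = seed_fc_map(run, [0, 1])
        m1 = seed_fc_map(run, [0])
        others = np.arange(2, 10)
        np.testing.assert_allclose(m2.r[others], m1.r[others], atol=1e-12)

    def test_three_voxel_seed_matches_brute_force(self, rng):
        run = make_run(rng.standard_normal((15, 70)))
        seed = [2, 5, 9]
        m = seed_fc_map(run, seed)
        C = np.corrcoef(run.data)
        for i in range(15):
            if i in seed:
                expect = np.mean([C[i, j] for j in seed if j != i])
            else:
                expect = np.mean([C[i, j] for j in seed])
            assert abs(m.r[i] - expect) < 1e-10

    def test_zero_variance_seed_voxel_excluded(self, rng):
        data = rng.standard_normal((8, 50))
        data[0] = 1.0
        run = make_run(data)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = seed_fc_map(run, [0, 1])
        np.testing.assert_allclose(m.r[2:], seed_fc_map(run, [1]).r[2:])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                seed_fc_map(run, [0])


class TestPhaseEffectSize:
    def test_hand_computed_pooled_sd_example(self):
        maps = [fc([v], f"a{v}", "cast") for v in (1.0, 2.0, 3.0)]
        maps += [fc([v], f"b{v}", "pre") for v in (4.0, 5.0, 6.0)]
        eff = phase_effect_size(maps, "cast", "pre")
        assert eff.d[0] == pytest.approx(-3.0)

    def test_swapping_phases_negates_d(self, rng):
        maps = [fc(rng.standard_normal(6), f"s{i}", "cast") for i in range(4)]
        maps += [fc(rng.standard_normal(6), f"p{i}", "pre") for i in range(4)]
        d1 = phase_effect_size(maps, "cast", "pre").d
        d2 = phase_effect_size(maps, "pre", "cast").d
        np.testing.assert_allclose(d1, -d2)

    def test_identical_sessions_flagged_undefined(self):
        maps = [fc([0.5], f"s{i}", "cast") for i in range(3)]
        maps += [fc([0.5], f"p{i}", "pre") for i in range(3)]
        eff = phase_effect_size(maps)
        assert np.isnan(eff.d[0])

    def test_too_few_sessions_rejected(self):
        maps = [fc([1.0], "a", "cast"), fc([0.0], "b", "pre"),
                fc([0.1], "c", "pre")]
        with pytest.raises(ValueError):
            phase_effect_size(maps)


class TestPermutationClusterCorrect:
    def test_identity_relabeling_reproduces_observed_d(self, rng):
        R = rng.standard_normal((8, 20))
        mask = np.array([True] * 4 + [False] * 4)
        d1 = _cohens_d(R, mask, ~mask)
        d2 = _cohens_d(R, mask.copy(), ~mask.copy())
        np.testing.assert_array_equal(d1, d2)

    def test_nperm_zero_rejected_and_small_warns(self, tiny_space, rng):
        maps = [fc(rng.standard_normal(tiny_space.n), f"c{i}", "cast")
                for i in range(3)]
        maps += [fc(rng.standard_normal(tiny_space.n), f"p{i}", "pre")
                 for i in range(3)]
        with pytest.raises(ValueError):
            permutation_cluster_correct(maps, tiny_space, n_perm=0)
        with pytest.warns(UserWarning, match="poorly resolved"):
            permutation_cluster_correct(maps, tiny_space, n_perm=20, seed=0)

    def test_clusters_never_span_structures_and_are_connected(self):
        params = SimParams()
        space = make_space(params, 0)
        truth = make_truth(space, params, 0)
        maps = []
        for phase in ("pre", "cast"):
            for i in range(params.sessions_per_phase):
                sid = f"{phase}-{i}"
                run = simulate_run(space, sid, phase, 0, params, truth,
                                   seed=child_seed(42, sid))
                maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
        res = permutation_cluster_correct(maps, space, n_perm=150, seed=0)
        assert res.significant
        from scipy.sparse.csgraph import connected_components
        for c in res.clusters:
            labels = set(space.structure_label[c.members].tolist())
            assert labels == {c.structure}
            sub = space.adjacency[np.ix_(c.members, c.members)]
            ncomp, _ = connected_components(sub, directed=False)
            assert ncomp == 1
            assert 0 < c.p_value <= 1
            assert c.n_thresholds_passed >= 2

    def test_membership_invariant_to_relabeling(self, rng):
        """Permuting grayordinate order permutes cluster membership
        consistently (graph isomorphism on a small instance)."""
        params = SimParams(cortex_shape=(6, 6), thalamus_shape=(3, 3, 3),
                           putamen_shape=(2, 2, 2), pallidum_shape=(2, 2, 2),
                           caudate_shape=(2, 2, 2), cerebellum_shape=(2, 2, 2),
                           T=120, sessions_per_phase=3, fc_blob_size=15)
        space = make_space(params, 0)
        truth = make_truth(space, params, 0)
        maps = []
        for phase in ("pre", "cast"):
            for i in range(3):
                sid = f"{phase}-{i}"
                run = simulate_run(space, sid, phase, 0, params, truth,
                                   seed=child_seed(7, sid))
                maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
        res1 = permutation_cluster_correct(maps, space, n_perm=100, seed=5)
        # relabel: reverse order within the thalamus-left block
        perm = np.arange(space.n)
        th = space.indices("thalamus-left")
        perm[th] = th[::-1]
        import scipy.sparse as sp
        from disuse.space import GrayordinateSpace
        P = sp.csr_matrix((np.ones(space.n), (np.arange(space.n), perm)),
                          shape=(space.n, space.n))
        space2 = GrayordinateSpace(
            coords=space.coords[perm], structure_label=space.structure_label[perm],
            adjacency=(P @ space.adjacency @ P.T).astype(bool),
            kind=space.kind[perm], snr=None,
            voxel_size_mm=space.voxel_size_mm,
        )
        maps2 = [FCMap(r=m.r[perm], session_id=m.session_id, phase=m.phase)
                 for m in maps]
        res2 = permutation_cluster_correct(maps2, space2, n_perm=100, seed=5)
        assert len(res1.clusters) == len(res2.clusters)
        assert sorted(c.size for c in res1.clusters) == \
            sorted(c.size for c in res2.clusters)
        # membership maps through the relabeling
        relabeled = sorted(tuple(sorted(perm[c.members])) for c in res2.clusters)
        original = sorted(tuple(sorted(c.members)) for c in res1.clusters)
        assert relabeled == original

    def test_monotone_power_in_effect_size(self):
        """A larger injected d never yields fewer significant voxels on
        average (checked over seeds)."""
        counts = {}
        for d in (1.0, 3.5):
            tot = 0
            params = SimParams(effect_d=d)
            space = make_space(params, 0)
            for rep in range(4):
                truth = make_truth(space, params, rep)
                maps = []
                for phase in ("pre", "cast"):
                    for i in range(params.sessions_per_phase):
                        sid = f"{phase}-{i}"
                        run = simulate_run(space, sid, phase, 0, params,
                                           truth,
                                           seed=child_seed(rep * 5 + 1, sid))
                        maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
                res = permutation_cluster_correct(maps, space, n_perm=100,
                                                  seed=rep)
                tot += sum(c.size for c in res.clusters)
            counts[d] = tot
        assert counts[3.5] >= counts[1.0]
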