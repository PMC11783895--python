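"""Rigid superposition, Butina clustering and the blocked-split recipe."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from flexfrag.generator import ConformerSpec, generate_class_ensemble
from flexfrag.split import (SplitParams, build_baseline_split, butina_cluster,
                            pairwise_rmsd, random_split, subcluster,
                            superpose_rmsd)


def _grid_search_rmsd(a, b):
    """Brute-force minimization over sampled rotations (oracle).

    Coarse random sampling of SO(3) followed by shrinking local
    perturbations around the best candidate; no closed-form step involved.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(r):
        d = a - b @ r.T
        return np.sqrt((d * d).sum() / len(a))

    rng = np.random.default_rng(0)
    candidates = Rotation.random(5000, random_state=rng)
    costs = [cost(r) for r in candidates.as_matrix()]
    best_rot = candidates[int(np.argmin(costs))]
    best = min(costs)
    for scale in (0.3, 0.1, 0.03, 0.01, 0.003, 0.001, 0.0003):
        for _ in range(300):
            trial = best_rot * Rotation.from_rotvec(
                rng.normal(scale=scale, size=3))
            c = cost(trial.as_matrix())
            if c < best:
                best, best_rot = c, trial
    return best


class TestSuperpose:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).normal(size=(8, 3))
        assert superpose_rmsd(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        r = Rotation.random(random_state=rng).as_matrix()
        b = a @ r.T + np.array([5.0, -3.0, 11.0])
        assert superpose_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        square = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        bent = square.copy()
        bent[2, 2] = 1.0  # displace one corner 1 A out of plane
        ours = superpose_rmsd(square, bent)
        oracle = _grid_search_rmsd(square, bent)
        assert ours <= oracle + 1e-6  # we find the true minimum
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPairwise:
    def test_identical_conformers_zero_matrix(self):
        c = np.tile(np.random.default_rng(2).normal(size=(1, 6, 3)),
                    (5, 1, 1))
        m, kept = pairwise_rmsd(c, seed=0)
        assert np.allclose(m, 0, atol=1e-9)
        assert len(kept) == 5

    def test_symmetry_and_diagonal(self, met_ensemble):
        c = np.stack([f.coords[f.heavy_mask] for f in met_ensemble[:10]])
        m, _ = pairwise_rmsd(c, seed=0)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert (m[~np.eye(10, dtype=bool)] > 0).all()

    def test_cap_limits_output(self, met_ensemble):
        c = np.stack([f.coords[f.heavy_mask] for f in met_ensemble])
        m, kept = pairwise_rmsd(c, cap=12, seed=3)
        assert m.shape == (12, 12)
        assert len(set(kept)) == 12

    def test_matches_pairwise_kabsch(self, met_ensemble):
        c = np.stack([f.coords[f.heavy_mask] for f in met_ensemble[:6]])
        m, _ = pairwise_rmsd(c, seed=0)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(
                    superpose_rmsd(c[i], c[j]), abs=1e-6)


class TestButina:
    def test_line_example(self):
        pos = np.array([0.0, 1, 2, 10, 11])
        d = np.abs(pos[:, None] - pos[None, :])
        clusters = butina_cluster(d, 1.5)
        assert sorted(map(tuple, clusters)) == [(0, 1, 2), (3, 4)]

    def test_huge_threshold_single_cluster(self):
        d = np.abs(np.arange(6.0)[:, None] - np.arange(6.0)[None, :])
        clusters = butina_cluster(d, 100.0)
        assert clusters == [[0, 1, 2, 3, 4, 5]]

    def test_zero_threshold_all_singletons(self):
        d = np.abs(np.arange(5.0)[:, None] - np.arange(5.0)[None, :])
        clusters = butina_cluster(d, 0.0)
        assert sorted(c[0] for c in clusters) == [0, 1, 2, 3, 4]
        assert all(len(c) == 1 for c in clusters)

    def test_partition_and_order(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(40, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        clusters = butina_cluster(d, 0.8)
        flat = [i for c in clusters for i in c]
        assert sorted(flat) == list(range(40))
        sizes = [len(c) for c in clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1], [2, 0]])
        with pytest.raises(ValueError):
            butina_cluster(d, 1.0)


class TestSubcluster:
    @staticmethod
    def _two_blob_matrix(n=40, sep=50.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        pts[n // 2:, 0] += sep
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return d, np.array([0] * (n // 2) + [1] * (n // 2))

    def test_blob_purity(self):
        d, blob = self._two_blob_matrix()
        labels = subcluster(d, k=10, seed=0)
        for g in range(10):
            members = blob[labels == g]
            if len(members):
                assert len(set(members)) == 1

    def test_deterministic(self):
        d, _ = self._two_blob_matrix(seed=1)
        a = subcluster(d, k=10, seed=5)
        b = subcluster(d, k=10, seed=5)
        assert np.array_equal(a, b)

    def test_k_nonempty_groups(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(100, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = subcluster(d, k=10, seed=0)
        assert len(set(labels)) == 10

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            subcluster(np.zeros((8, 8)), k=10)


class TestBaselineSplit:
    def test_degenerate_identical_conformers(self):
        c = np.tile(np.random.default_rng(7).normal(size=(1, 5, 3)),
                    (100, 1, 1))
        recs = build_baseline_split(c, label="ALA", seed=0)
        counts = {a: sum(r.assignment == a for r in recs)
                  for a in ("train", "test", "excluded")}
        assert counts == {"train": 10, "test": 5, "excluded": 85}

    def test_bottom_quartile_cluster_is_test_only(self):
        # 4 well-separated blobs of 50 pseudo-conformers each
        rng = np.random.default_rng(8)
        base = rng.normal(size=(4, 6, 3)) * 8
        coords = np.concatenate([
            base[k][None] + rng.normal(scale=0.05, size=(50, 6, 3))
            for k in range(4)])
        recs = build_baseline_split(coords, label="X", seed=1)
        dist, _ = pairwise_rmsd(coords, seed=1)
        clusters = {}
        for r in recs:
            clusters.setdefault(r.cluster, []).append(r)
        assert len(clusters) == 4
        bottom = max(clusters)  # clusters are rank-ordered by size
        assert all(r.assignment in ("test", "excluded")
                   for r in clusters[bottom])
        assert any(r.assignment == "test" for r in clusters[bottom])

    def test_partition_invariant(self, met_ensemble):
        c = np.stack([f.coords[f.heavy_mask] for f in met_ensemble])
        for seed in (0, 1, 2):
            recs = build_baseline_split(c, label="MET", seed=seed)
            train = {r.sample_id for r in recs if r.assignment == "train"}
            test = {r.sample_id for r in recs if r.assignment == "test"}
            assert not train & test
            assert len(recs) == len(c)

    def test_subcluster_caps(self):
        # one large diverse cluster exercises the subcluster path
        ens = generate_class_ensemble(
            ConformerSpec("SER", 80, seed=3, mode="k_modes", n_modes=1,
                          spread=25.0))
        c = np.stack([f.coords[f.heavy_mask] for f in ens])
        recs = build_baseline_split(c, label="SER", seed=0)
        by_cluster = {}
        for r in recs:
            by_cluster.setdefault(r.cluster, []).append(r)
        for members in by_cluster.values():
            n_tr = sum(r.assignment == "train" for r in members)
            n_te = sum(r.assignment == "test" for r in members)
            assert n_tr <= 10 and n_te <= 5
            by_sub = {}
            for r in members:
                if r.subcluster is not None:
                    by_sub.setdefault(r.subcluster, []).append(r)
            for sub in by_sub.values():
                assert sum(r.assignment == "train" for r in sub) <= 10
                assert sum(r.assignment == "test" for r in sub) <= 5

    def test_blocked_beats_random_on_bimodal(self):
        margins = []
        for seed in range(8):
            ens = generate_class_ensemble(
                ConformerSpec("MET", 90, seed=200 + seed, mode="k_modes",
                              n_modes=2, spread=8.0))
            c = np.stack([f.coords[f.heavy_mask] for f in ens])
            d, _ = pairwise_rmsd(c, seed=seed)
            recs = build_baseline_split(c, label="MET", seed=seed, dist=d)
            tr = [r.sample_id for r in recs if r.assignment == "train"]
            te = [r.sample_id for r in recs if r.assignment == "test"]
            rr = random_split(len(c), len(tr), len(te), seed=seed)
            rtr = [r.sample_id for r in rr if r.assignment == "train"]
            rte = [r.sample_id for r in rr if r.assignment == "test"]
            margins.append(d[np.ix_(te, tr)].min()
                           - d[np.ix_(rte, rtr)].min())
        assert np.mean(margins) > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            build_baseline_split(np.zeros((1, 4, 3)), seed=0)


@settings(deadline=None, max_examples=20)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_split_partition_property(seed):
    """Train and test never overlap, whatever the conformer geometry."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=rng.uniform(0.01, 3.0), size=(25, 5, 3))
    recs = build_baseline_split(coords, label="P", seed=seed % 1000)
    train = {r.sample_id for r in recs if r.assignment == "train"}
    test = {r.sample_id for r in recs if r.assignment == "test"}
    assert not train & test
    assert {r.sample_id for r in recs} == set(range(25))
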