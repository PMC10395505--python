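"""Segmentation heads, weak-supervision losses, clustering and inference."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from shootseg.cloud import LEAF, STEM, UNLABELED, LabeledPointCloud, ValidationError
from shootseg.io import make_weak_annotation
from shootseg.segmentation import (
    ClusterSet,
    FinetuneConfig,
    MLPHead,
    Proposal,
    SegmentationModel,
    ball_cluster,
    build_instance_supervision,
    finetune,
    infer,
    instance_loss,
    masked_cross_entropy,
    merge_proposals,
    offset_direction_loss,
    offset_regression_loss,
    semantic_predict,
)
from shootseg.segmentation import InstanceSupervision
from shootseg.synthetic import PlantSpec, generate_dataset, generate_plant
from shootseg.voxelnet import BackboneConfig


class TestSemanticPredict:
    def test_one_hot_scores_give_hot_label(self, rng):
        head = MLPHead(rng, 4, 3)
        feats = rng.normal(size=(10, 4))
        pred = semantic_predict(feats, head)
        assert pred.scores.shape == (10, 3)
        assert pred.labels.shape == (10,)
        assert np.array_equal(pred.labels, np.argmax(pred.scores, axis=1))

    def test_tie_goes_to_lowest_class(self):
        scores = np.array([[0.5, 0.5], [0.1, 0.9]])
        assert np.argmax(scores, axis=1).tolist() == [0, 1]  # documented numpy tie rule
        labels = np.argmax(scores, axis=1)
        assert labels[0] == 0


class TestMaskedCrossEntropy:
    def test_confident_correct_is_near_zero(self):
        scores = np.array([[100.0, 0.0], [0.0, 100.0]])
        gt = np.array([0, 1])
        assert masked_cross_entropy(scores, gt) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((7, 2))
        gt = np.array([0, 1, 0, 1, 0, 1, 0])
        assert masked_cross_entropy(scores, gt) == pytest.approx(np.log(2.0))

    def test_unlabeled_points_contribute_nothing(self, rng):
        scores = rng.normal(size=(20, 2))
        gt = np.full(20, UNLABELED)
        gt[:5] = rng.integers(0, 2, size=5)
        ref = masked_cross_entropy(scores, gt)
        scores2 = scores.copy()
        scores2[5:] = rng.normal(size=(15, 2)) * 100
        assert masked_cross_entropy(scores2, gt) == pytest.approx(ref)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            masked_cross_entropy(np.zeros((3, 2)), np.full(3, UNLABELED))


class TestInstanceSupervision:
    def test_single_leaf_centroid(self):
        coords = np.arange(30, dtype=float).reshape(10, 3)
        cloud = LabeledPointCloud(coords, semantic=np.full(10, LEAF),
                                  instance=np.ones(10, dtype=int))
        sup = build_instance_supervision(cloud)
        assert np.all(sup.mask)
        assert np.allclose(sup.centroids, coords.mean(axis=0))

    def test_stem_only_annotations_rejected(self):
        cloud = LabeledPointCloud(np.zeros((5, 3)), semantic=np.full(5, STEM),
                                  instance=np.zeros(5, dtype=int))
        with pytest.raises(ValidationError):
            build_instance_supervision(cloud)

    def test_two_instances_per_instance_means(self, rng):
        coords = rng.normal(size=(20, 3))
        inst = np.array([1] * 8 + [2] * 12)
        cloud = LabeledPointCloud(coords, semantic=np.full(20, LEAF), instance=inst)
        sup = build_instance_supervision(cloud)
        for iid in (1, 2):
            direct = coords[inst == iid].mean(axis=0)  # oracle: direct averaging
            assert np.allclose(sup.centroids[inst == iid], direct)


def _sup(mask, centroids):
    return InstanceSupervision(mask=np.asarray(mask, bool), centroids=np.asarray(centroids, float))


class TestOffsetLosses:
    def test_perfect_offsets_zero_regression(self, rng):
        coords = rng.normal(size=(6, 3))
        cent = np.tile(rng.normal(size=3), (6, 1))
        o = cent - coords
        sup = _sup(np.ones(6), cent)
        assert offset_regression_loss(o, coords, sup) == pytest.approx(0.0)
        assert offset_direction_loss(o, coords, sup) == pytest.approx(-1.0)

    def test_single_point_l1(self):
        coords = np.zeros((1, 3))
        sup = _sup([1], [[0.0, 1.0, 0.0]])
        o = np.array([[1.0, 0.0, 0.0]])
        assert offset_regression_loss(o, coords, sup) == pytest.approx(2.0)

    def test_direction_cosine_values(self):
        coords = np.zeros((1, 3))
        sup = _sup([1], [[1.0, 0.0, 0.0]])
        assert offset_direction_loss(np.array([[0.0, 1.0, 0.0]]), coords, sup) == pytest.approx(0.0)
        assert offset_direction_loss(np.array([[-2.0, 0.0, 0.0]]), coords, sup) == pytest.approx(1.0)

    def test_zero_norm_offset_skipped_with_warning(self):
        coords = np.zeros((2, 3))
        sup = _sup([1, 1], [[1.0, 0, 0], [1.0, 0, 0]])
        o = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            val = offset_direction_loss(o, coords, sup)
        assert val == pytest.approx(-0.5)  # one aligned point over sum(m)=2

    def test_losses_match_loop_oracle(self, rng):
        coords = rng.normal(size=(15, 3))
        cent = rng.normal(size=(15, 3))
        o = rng.normal(size=(15, 3))
        mask = rng.integers(0, 2, size=15).astype(bool)
        mask[0] = True
        sup = _sup(mask, cent)
        reg, dire, m_sum = 0.0, 0.0, mask.sum()
        for i in range(15):
            if mask[i]:
                t = cent[i] - coords[i]
                reg += np.abs(o[i] - t).sum()
                dire += -np.dot(o[i] / np.linalg.norm(o[i]), t / np.linalg.norm(t))
        assert offset_regression_loss(o, coords, sup) == pytest.approx(reg / m_sum)
        assert offset_direction_loss(o, coords, sup) == pytest.approx(dire / m_sum)

    def test_reordering_invariance(self, rng):
        coords = rng.normal(size=(12, 3))
        cent = rng.normal(size=(12, 3))
        o = rng.normal(size=(12, 3))
        sup = _sup(np.ones(12), cent)
        perm = rng.permutation(12)
        sup_p = _sup(np.ones(12), cent[perm])
        assert offset_regression_loss(o[perm], coords[perm], sup_p) == pytest.approx(
            offset_regression_loss(o, coords, sup)
        )


def test_instance_loss_is_unit_weight_sum():
    assert instance_loss(0.0, 0.0, -1.0) == -1.0
    assert instance_loss(0.7, 0.2, -0.5) == pytest.approx(0.4)


class TestBallCluster:
    def test_chain_connectivity(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        cs = ball_cluster(coords, np.full(10, LEAF), radius=1.5, min_size=1)
        assert len(cs) == 1
        assert len(cs.proposals[0].indices) == 10

    def test_two_separated_groups(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        b = a + np.array([20.0, 0, 0])
        cs = ball_cluster(np.vstack([a, b]), np.full(10, LEAF), radius=1.5, min_size=1)
        assert len(cs) == 2

    def test_stem_points_never_cluster(self):
        coords = np.zeros((5, 3))
        cs = ball_cluster(coords, np.full(5, STEM), radius=1.5, min_size=1)
        assert len(cs) == 0

    def test_matches_bruteforce_components(self, rng):
        coords = rng.uniform(0, 20, size=(200, 3))
        sem = rng.choice([STEM, LEAF], size=200)
        cs = ball_cluster(coords, sem, radius=2.5, min_size=1)
        # O(N^2) oracle: union-find over the pairwise-distance graph
        leaf_idx = np.flatnonzero(sem == LEAF)
        parent = {i: i for i in leaf_idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        d = cdist(coords[leaf_idx], coords[leaf_idx])
        for a in range(len(leaf_idx)):
            for b in range(a + 1, len(leaf_idx)):
                if d[a, b] <= 2.5:
                    parent[find(leaf_idx[a])] = find(leaf_idx[b])
        oracle = {}
        for i in leaf_idx:
            oracle.setdefault(find(i), set()).add(i)
        got = {frozenset(p.indices.tolist()) for p in cs.proposals}
        assert got == {frozenset(s) for s in oracle.values()}

    def test_partition_and_order_invariance(self, rng):
        coords = rng.uniform(0, 15, size=(150, 3))
        sem = np.full(150, LEAF)
        cs = ball_cluster(coords, sem, radius=2.0, min_size=1)
        all_idx = np.concatenate([p.indices for p in cs.proposals])
        assert sorted(all_idx) == list(range(150))
        perm = rng.permutation(150)
        cs_p = ball_cluster(coords[perm], sem, radius=2.0, min_size=1)
        got = {frozenset(perm[p.indices].tolist()) for p in cs_p.proposals}
        assert got == {frozenset(p.indices.tolist()) for p in cs.proposals}


class TestMergeProposals:
    def _cs(self, sets, confs, tag):
        return ClusterSet(
            [Proposal(np.array(s), LEAF, c) for s, c in zip(sets, confs)], tag
        )

    def test_disjoint_all_survive(self):
        cc = self._cs([[0, 1, 2]], [1.0], "Cc")
        cs = self._cs([[5, 6, 7]], [0.8], "Cs")
        merged = merge_proposals(cc, cs)
        assert len(merged) == 2

    def test_identical_proposal_deduplicated(self):
        cc = self._cs([[0, 1, 2, 3]], [1.0], "Cc")
        cs = self._cs([[0, 1, 2, 3]], [0.9], "Cs")
        merged = merge_proposals(cc, cs)
        assert len(merged) == 1
        assert merged.proposals[0].confidence == 1.0

    def test_iou_above_half_keeps_higher_confidence(self):
        # IoU = 6/10 = 0.6 between an 8-set and a 8-set sharing 6
        a = list(range(8))
        b = list(range(2, 10))
        cc = self._cs([a], [1.0], "Cc")
        cs = self._cs([b], [0.7], "Cs")
        merged = merge_proposals(cc, cs)
        assert len(merged) == 1
        assert set(merged.proposals[0].indices) == set(a)

    def test_merged_proposals_are_disjoint(self, rng):
        sets_a = [rng.choice(100, size=30, replace=False) for _ in range(3)]
        sets_b = [rng.choice(100, size=25, replace=False) for _ in range(3)]
        merged = merge_proposals(
            self._cs(sets_a, [1.0, 0.9, 0.8], "Cc"),
            self._cs(sets_b, [0.95, 0.85, 0.75], "Cs"),
        )
        seen = set()
        for p in merged.proposals:
            assert not (seen & set(p.indices.tolist()))
            seen |= set(p.indices.tolist())


@pytest.fixture(scope="module")
def tiny_weak():
    ds = generate_dataset(
        4, {"points_per_organ": 200, "n_leaves": (2, 3), "noise_sigma": 0.0}, seed=5
    )
    weak = [make_weak_annotation(c, 50, seed=i) for i, (c, _) in enumerate(ds)]
    bb = BackboneConfig(channels=(8, 16), out_dim=8, seed=0)
    return ds, weak, bb


class TestFinetuneInfer:

    def test_seeded_rerun_identical_loss_trace(self, tiny_weak):
        _, weak, bb = tiny_weak
        cfg = FinetuneConfig(iterations=15, lr=0.03, seed=0)
        _, h1 = finetune(weak, None, "semantic", cfg, backbone_config=bb)
        _, h2 = finetune(weak, None, "semantic", cfg, backbone_config=bb)
        assert h1 == h2

    def test_semantic_training_loss_decreases(self, tiny_weak):
        _, weak, bb = tiny_weak
        _, hist = finetune(weak, None, "semantic",
                           FinetuneConfig(iterations=60, lr=0.03, seed=0),
                           backbone_config=bb)
        assert hist[-1] < hist[0]

    def test_infer_totality_and_disjoint_instances(self, tiny_weak, tmp_path):
        ds, weak, bb = tiny_weak
        cfg = FinetuneConfig(iterations=40, lr=0.03, seed=0, min_cluster_size=20)
        model, _ = finetune(weak, None, "instance", cfg, backbone_config=bb)
        cloud = ds[0][0]
        pred, clusters, inst = infer(cloud, model)
        assert pred.labels.shape == (len(cloud),)
        assert inst.shape == (len(cloud),)
        seen = set()
        for p in clusters.proposals:
            assert not (seen & set(p.indices.tolist()))
            seen |= set(p.indices.tolist())
        # checkpoint roundtrip keeps predictions
        path = tmp_path / "inst.npz"
        model.save(path)
        model2 = SegmentationModel.load(path)
        pred2, _, inst2 = infer(cloud, model2)
        assert np.array_equal(pred.labels, pred2.labels)
        assert np.array_equal(inst, inst2)

    def test_unlabeled_training_cloud_rejected(self, tiny_weak):
        _, weak, bb = tiny_weak
        bare = LabeledPointCloud(np.random.default_rng(0).normal(size=(30, 3)))
        with pytest.raises(ValidationError):
            finetune([bare], None, "semantic", FinetuneConfig(iterations=2),
                     backbone_config=bb)


def test_oracle_semantic_zero_offsets_recovers_two_leaves():
    """With ground-truth semantics and zero offsets, dual-coordinate
    clustering on a clean 2-leaf plant returns exactly the 2 leaves."""
    cloud, _ = generate_plant(PlantSpec(n_leaves=2, noise_sigma=0.0, seed=9))
    offsets = np.zeros_like(cloud.coords)
    cc = ball_cluster(cloud.coords, cloud.semantic, 1.5, 50, "Cc")
    cs = ball_cluster(cloud.coords + offsets, cloud.semantic, 1.5, 50, "Cs")
    merged = merge_proposals(cc, cs)
    assert len(merged) == 2
    got = {frozenset(p.indices.tolist()) for p in merged.proposals}
    want = {
        frozenset(np.flatnonzero(cloud.instance == iid).tolist()) for iid in (1, 2)
    }
    assert got == want
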