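import math

import numpy as np
import pytest

from qwpso import (
    ANGLE_MAX_DEG,
    Cluster,
    ClusterParams,
    ParameterError,
    QwpsoConfig,
    WormholeParams,
    merge_via_wormhole,
    pixel_absorbed_by_seed,
    pixels_entangled,
    qpso_segment,
    qwpso_segment,
    wormhole_exists,
)
from qwpso.metrics import confusion, precision_recall_f
from qwpso.phantoms import PhantomSpec, make_phantom


def _flat(h, w, value=100):
    return np.full((h, w), value, dtype=np.uint8)


class TestPixelsEntangled:
    def test_same_pixel_always_entangled(self):
        img = _flat(4, 4)
        assert pixels_entangled((1, 1), (1, 1), img, ClusterParams(th_f=0, th_o=0))

    def test_gray_difference_blocks_regardless_of_distance(self):
        img = _flat(4, 4)
        img[0, 0], img[0, 1] = 100, 150
        assert not pixels_entangled((0, 0), (0, 1), img, ClusterParams(th_f=10, th_o=5))

    def test_distance_boundary_inclusive(self):
        img = _flat(8, 8)
        cp = ClusterParams(th_f=10, th_o=5)
        assert pixels_entangled((0, 0), (3, 4), img, cp)  # 3-4-5 triangle, d = 5
        assert not pixels_entangled((0, 0), (3, 5), img, cp)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ParameterError):
            pixels_entangled((0, 0), (9, 9), _flat(4, 4), ClusterParams())


class TestPixelAbsorbedBySeed:
    def test_adjacent_matching_pixel_absorbed(self):
        img = _flat(4, 4)
        c = Cluster.from_members(1, {(1, 1)}, img)
        assert pixel_absorbed_by_seed((1, 2), c, img, ClusterParams(th_f=10, th_o=3))

    def test_gray_boundary_inclusive(self):
        img = _flat(4, 4)
        img[1, 2] = 110
        c = Cluster.from_members(1, {(1, 1)}, img)
        assert pixel_absorbed_by_seed((1, 2), c, img, ClusterParams(th_f=10, th_o=3))

    def test_distance_to_nearest_member_governs(self):
        img = _flat(1, 8)
        c = Cluster.from_members(1, {(0, 0)}, img)
        assert not pixel_absorbed_by_seed((0, 6), c, img, ClusterParams(th_f=10, th_o=5))


class TestWormholeExists:
    def _clusters(self, img, a_members, b_members):
        return (
            Cluster.from_members(1, a_members, img),
            Cluster.from_members(2, b_members, img),
        )

    def test_singletons_cannot_open_a_wormhole(self):
        img = _flat(64, 64)
        a, b = self._clusters(img, {(5, 5)}, {(50, 50)})
        assert not wormhole_exists(a, b, img, ClusterParams(), WormholeParams())

    def test_neighbors_cannot_open_a_wormhole(self):
        img = _flat(64, 64)
        a, b = self._clusters(img, {(5, 5), (5, 6)}, {(5, 7), (5, 8)})
        assert not wormhole_exists(a, b, img, ClusterParams(th_o=3), WormholeParams())

    def test_distant_similar_clusters_connect(self):
        img = _flat(64, 64)
        a, b = self._clusters(
            img, {(10, 31), (10, 32), (11, 32)}, {(50, 31), (50, 32), (51, 32)}
        )
        assert wormhole_exists(a, b, img, ClusterParams(), WormholeParams())

    def test_dissimilar_grays_block(self):
        img = _flat(64, 64)
        img[50:52, 31:33] = 200
        a, b = self._clusters(
            img, {(10, 31), (10, 32)}, {(50, 31), (50, 32), (51, 31), (51, 32)}
        )
        assert not wormhole_exists(a, b, img, ClusterParams(th_f=10), WormholeParams())


class TestMergeViaWormhole:
    def test_weighted_mean(self):
        img = _flat(8, 8)
        img[0, 0] = img[0, 1] = 100
        img[5, 0] = img[5, 1] = 110
        a = Cluster.from_members(1, {(0, 0), (0, 1)}, img)
        b = Cluster.from_members(2, {(5, 0), (5, 1)}, img)
        m = merge_via_wormhole(a, b)
        assert m.mean_gray == pytest.approx(105.0)
        assert m.size == 4
        assert m.kind == "seed"

    def test_equal_means_unchanged(self):
        img = _flat(8, 8)
        a = Cluster.from_members(1, {(0, 0)}, img)
        b = Cluster.from_members(2, {(7, 7)}, img)
        assert merge_via_wormhole(a, b).mean_gray == pytest.approx(100.0)

    def test_overlap_rejected(self):
        img = _flat(8, 8)
        a = Cluster.from_members(1, {(0, 0), (1, 1)}, img)
        b = Cluster.from_members(2, {(1, 1), (2, 2)}, img)
        with pytest.raises(ParameterError):
            merge_via_wormhole(a, b)


class TestQwpsoSegment:
    def test_constant_image_degenerates_to_one_cluster(self):
        img = _flat(24, 24, 128)
        res = qwpso_segment(img, QwpsoConfig(seed=2))
        assert len(res.clusters) == 1
        assert not res.foreground.any()

    def test_noiseless_dualtail_recovered_with_tail_tips(self):
        img, truth = make_phantom(PhantomSpec(shape="dualtail", size=64, tail_length=15))
        res = qwpso_segment(img, QwpsoConfig(seed=1))
        _, _, f = precision_recall_f(confusion(res.foreground, truth))
        assert f == 1.0
        cols = np.nonzero(truth.any(axis=0))[0]
        for col in (cols[0], cols[-1]):  # both tail tips
            rows = np.nonzero(truth[:, col])[0]
            assert res.foreground[rows[0], col]

    def test_gap_bottleneck_joined_only_via_wormhole(self, gap_bottleneck):
        """With the wormhole branch the two lobes end in one cluster; the
        identical run without it leaves them separate and scores lower."""
        img, truth = gap_bottleneck
        cfg = QwpsoConfig(seed=0)
        rw = qwpso_segment(img, cfg)
        rq = qwpso_segment(img, cfg.disabled())
        fw = precision_recall_f(confusion(rw.foreground, truth))[2]
        fq = precision_recall_f(confusion(rq.foreground, truth))[2]
        assert fw > fq
        bright_w = [c for c in rw.clusters if c.mean_gray > 125]
        bright_q = [c for c in rq.clusters if c.mean_gray > 125]
        assert len(bright_w) == 1
        assert len(bright_q) == 2

    def test_determinism_bitwise(self, suite):
        img, _, _ = suite[1]
        a = qwpso_segment(img, QwpsoConfig(seed=4))
        b = qwpso_segment(img, QwpsoConfig(seed=4))
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.foreground, b.foreground)
        assert a.log == b.log

    def test_disabled_wormhole_equals_qpso_engine(self, suite):
        img, _, _ = suite[5]
        r1 = qwpso_segment(img, QwpsoConfig(seed=6).disabled())
        r2 = qpso_segment(img, seed=6)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.foreground, r2.foreground)


@pytest.fixture(scope="module")
def result_and_inputs():
    img, _ = make_phantom(
        PhantomSpec(shape="bottleneck", size=64, neck_width=3, noise_sd=10, seed=2)
    )
    cfg = QwpsoConfig(seed=3)
    return img, cfg, qwpso_segment(img, cfg)


class TestResultInvariants:

    def test_every_pixel_labeled_once(self, result_and_inputs):
        _, _, res = result_and_inputs
        assert (res.labels >= 1).all()
        sizes = sum(c.size for c in res.clusters)
        assert sizes == res.labels.size

    def test_cluster_means_match_members_exactly(self, result_and_inputs):
        img, _, res = result_and_inputs
        for c in res.clusters:
            grays = [float(img[m]) for m in c.members]
            assert c.mean_gray == pytest.approx(np.mean(grays), abs=1e-9)
            rows = [m[0] for m in c.members]
            cols = [m[1] for m in c.members]
            assert c.centroid.row == pytest.approx(np.mean(rows), abs=1e-9)
            assert c.centroid.col == pytest.approx(np.mean(cols), abs=1e-9)

    def test_foreground_is_a_union_of_clusters(self, result_and_inputs):
        _, _, res = result_and_inputs
        fg_ids = set(np.unique(res.labels[res.foreground]))
        for cid in fg_ids:
            members = res.cluster_by_id(int(cid)).members
            assert all(res.foreground[m] for m in members)

    def test_log_replay_reconstructs_the_partition(self, result_and_inputs):
        """Replaying the admission/merge log must yield the same pixel
        partition as the returned label map."""
        img, cfg, res = result_and_inputs
        parent: dict[int, int] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        owner: dict[tuple, int] = {}
        for ev in res.log:
            kind = ev[0]
            if kind == "entangle":
                _, p1, p2, cid = ev
                parent[cid] = cid
                owner[p1] = cid
                owner[p2] = cid
            elif kind == "found":
                _, p, cid = ev
                parent[cid] = cid
                owner[p] = cid
            elif kind in ("absorb", "leftover"):
                p, cid = ev[1], ev[2]
                owner[p] = find(cid)
            elif kind == "wormhole":
                a, b = ev[1], ev[2]
                ra, rb = find(a), find(b)
                parent[max(ra, rb)] = min(ra, rb)
            elif kind == "coalesce":
                a, b = ev[1], ev[2]
                ra, rb = find(a), find(b)
                parent[max(ra, rb)] = min(ra, rb)
        assert len(owner) == res.labels.size
        # same partition: replayed roots <-> result labels are a bijection
        mapping: dict[int, int] = {}
        for p, cid in owner.items():
            root = find(cid)
            lab = int(res.labels[p])
            assert mapping.setdefault(root, lab) == lab
        assert len(set(mapping.values())) == len(mapping)

    def test_absorptions_respected_admission_rule(self, result_and_inputs):
        img, cfg, res = result_and_inputs
        for ev in res.log:
            if ev[0] == "absorb":
                _, p, _, mean_at_admission = ev
                assert abs(float(img[p]) - mean_at_admission) <= cfg.cluster.th_f
            elif ev[0] == "entangle":
                _, p1, p2, _ = ev
                assert abs(float(img[p1]) - float(img[p2])) <= cfg.cluster.th_f
                assert math.hypot(p1[0] - p2[0], p1[1] - p2[1]) <= cfg.cluster.th_o

    def test_wormhole_angles_stay_in_admissible_range(self, result_and_inputs):
        _, _, res = result_and_inputs
        assert res.delta_thetas, "wormhole updates should have occurred"
        arr = np.array(res.delta_thetas)
        assert (arr > 0).all() and (arr <= ANGLE_MAX_DEG).all()
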