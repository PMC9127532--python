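"""The QWPSO segmentation engine (and, with the wormhole branch disabled,
the QPSO baseline).

The engine maintains a swarm of M roaming particles over the image. At
each update one particle acts (round-robin), classified by the pixel it
stands on, and then moves, so the budget counts position updates:

* a **pixel particle** (unlabeled pixel) meets its spatially nearest
  entity. If that entity is another unlabeled particle and the two pixels
  pass the joint gray/distance entanglement test, they form a seed
  cluster. Otherwise the pixel is absorbed by the reachable cluster (a
  member within the distance threshold) whose running mean best matches
  its gray; if no cluster admits it, the particle founds a new singleton
  seed at its pixel. Either way it then moves by the QPSO update.
* a **seed particle** (labeled pixel) meets the foreign cluster closest
  in the *hidden* similarity metric — most similar mean gray among
  clusters that are *not* spatial neighbors, ties going to the farther
  one (wormholes link long-distance nodes). It moves along the wormhole
  update, and the two clusters are merged when the wormhole-existence
  test passes: both have at least two members, their means are similar
  while their centroids are outside the neighborhood radius, and the
  hyperbolic path measure connects them with sufficient probability.
  With the wormhole branch disabled the particle instead moves by the
  QPSO update and no long-range merging ever occurs. A seed particle
  whose move does not leave its pixel is re-dispersed uniformly
  (stagnation escape), which keeps pixel-particle traffic alive until
  the image is covered.

When every pixel is labeled, or the update budget is exhausted, leftover
pixels are attached to the cluster minimizing (gray difference, then
centroid distance), clusters that are both gray-similar and spatially
adjacent are coalesced, and the foreground is chosen by a between-class
threshold over cluster means: under bright-object polarity the largest
cluster on the bright side of the threshold is the object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .qpso import QpsoParams, SwarmState, local_attractor, qpso_update
from .types import (
    Cluster,
    ClusterParams,
    ParameterError,
    PixelPos,
    SegmentationResult,
    position_to_pixel,
)
from .wormhole import (
    WormholeParams,
    angular_separation,
    connection_probability,
    disc_embed,
    embed_point,
    hyperbolic_path_length,
    wormhole_update,
)


@dataclass(frozen=True)
class QwpsoConfig:
    """Full configuration of a segmentation run."""

    qpso: QpsoParams = field(default_factory=QpsoParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    wormhole: WormholeParams = field(default_factory=WormholeParams)
    polarity: str = "bright-object"
    seed: int = 0
    wormhole_enabled: bool = True

    def __post_init__(self) -> None:
        if self.polarity not in ("bright-object", "dark-object"):
            raise ParameterError(
                f"polarity must be 'bright-object' or 'dark-object', got {self.polarity!r}"
            )

    def disabled(self) -> "QwpsoConfig":
        """The identical configuration with the wormhole branch off."""
        return replace(self, wormhole_enabled=False)


# ---------------------------------------------------------------------------
# The entanglement and wormhole tests (public operations)
# ---------------------------------------------------------------------------

def pixels_entangled(
    p1: tuple[int, int], p2: tuple[int, int], image: np.ndarray, cp: ClusterParams
) -> bool:
    """Joint gray/distance entanglement test between two pixels.

    True iff |f1 - f2| <= th_f AND the Euclidean pixel distance <= th_o
    (both boundaries inclusive).
    """
    h, w = image.shape
    for p in (p1, p2):
        if not (0 <= p[0] < h and 0 <= p[1] < w):
            raise ParameterError(f"pixel {p} outside {h}x{w} image")
    df = abs(float(image[p1]) - float(image[p2]))
    dd = math.hypot(p1[0] - p2[0], p1[1] - p2[1])
    return df <= cp.th_f and dd <= cp.th_o


def pixel_absorbed_by_seed(
    p: tuple[int, int], cluster: Cluster, image: np.ndarray, cp: ClusterParams
) -> bool:
    """Absorption test of a pixel against a cluster.

    The gray test runs against the cluster's running mean; the distance
    test against the *nearest member pixel*, so absorption grows connected
    regions.
    """
    if not cluster.members:
        raise ParameterError("cluster must be non-empty")
    if abs(float(image[p]) - cluster.mean_gray) > cp.th_f:
        return False
    dmin = min(math.hypot(p[0] - m[0], p[1] - m[1]) for m in cluster.members)
    return dmin <= cp.th_o


def wormhole_exists(
    a: Cluster,
    b: Cluster,
    image: np.ndarray,
    cp: ClusterParams,
    wp: WormholeParams,
) -> bool:
    """The three conditions for a wormhole between two seed clusters.

    (1) each cluster holds at least two nodes; (2) the clusters are *not*
    spatial neighbors (centroid distance > th_o) but their gray means are
    similar (<= th_f); (3) the hyperbolic path measure connects them with
    probability >= connect_prob_min.
    """
    if a.id == b.id:
        raise ParameterError("wormhole requires two distinct clusters")
    if len(a.members) < 2 or len(b.members) < 2:
        return False
    if abs(a.mean_gray - b.mean_gray) > cp.th_f:
        return False
    cdist = math.hypot(a.centroid.row - b.centroid.row, a.centroid.col - b.centroid.col)
    if cdist <= cp.th_o:
        return False
    ca = disc_embed(a, image, wp.disc_radius)
    cb = disc_embed(b, image, wp.disc_radius)
    if wp.delta_theta_policy == "fixed":
        dtheta = wp.delta_theta_fixed
    else:
        dtheta = angular_separation(ca, cb)
    x = hyperbolic_path_length(ca.r, cb.r, dtheta, wp.zeta)
    return connection_probability(x, wp) >= wp.connect_prob_min


def merge_via_wormhole(a: Cluster, b: Cluster) -> Cluster:
    """Union two clusters; the mean is member-weighted, the kind is seed."""
    if a.id == b.id:
        raise ParameterError("cannot merge a cluster with itself")
    members = a.members | b.members
    na, nb = len(a.members), len(b.members)
    n = len(members)
    if n != na + nb:
        # overlapping members would double-count the running sums
        raise ParameterError("merge requires disjoint member sets")
    mean = (a.mean_gray * na + b.mean_gray * nb) / n
    centroid = PixelPos(
        (a.centroid.row * na + b.centroid.row * nb) / n,
        (a.centroid.col * na + b.centroid.col * nb) / n,
    )
    return Cluster(min(a.id, b.id), members, mean, centroid, kind="seed")


# ---------------------------------------------------------------------------
# Engine internals
# ---------------------------------------------------------------------------

def _window_offsets(th_o: float) -> np.ndarray:
    """Integer (dy, dx) offsets with 0 < hypot <= th_o."""
    r = int(math.ceil(th_o))
    out = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if (dy, dx) != (0, 0) and math.hypot(dy, dx) <= th_o
    ]
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _local_std(img: np.ndarray) -> np.ndarray:
    """3x3 local intensity standard deviation."""
    f = img.astype(np.float64)
    m = ndimage.uniform_filter(f, size=3, mode="nearest")
    m2 = ndimage.uniform_filter(f * f, size=3, mode="nearest")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: list[int] = [0]  # id 0 = unassigned sentinel

    def add(self) -> int:
        cid = len(self.parent)
        self.parent.append(cid)
        return cid

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        root, child = (ra, rb) if ra < rb else (rb, ra)
        self.parent[child] = root
        return root


class _Engine:
    def __init__(self, image: np.ndarray, config: QwpsoConfig):
        image = np.asarray(image)
        if image.ndim != 2 or image.size == 0:
            raise ParameterError(f"image must be a non-empty 2-D array, got shape {image.shape}")
        self.image = image.astype(np.uint8, copy=False)
        self.img = self.image.astype(np.float64)
        self.config = config
        self.cp = config.cluster
        self.wp = config.wormhole
        self.qp = config.qpso
        self.h, self.w = image.shape
        self.rng = np.random.default_rng(config.seed)
        self.labels = np.zeros((self.h, self.w), dtype=np.int32)
        self.uf = _UnionFind()
        # per-cluster running sums, indexed by raw cluster id (0 unused);
        # flat numpy arrays with capacity doubling keep per-step cost O(K)
        self._cap = 64
        self.gsum = np.zeros(self._cap)
        self.rsum = np.zeros(self._cap)
        self.csum = np.zeros(self._cap)
        self.size = np.zeros(self._cap, dtype=np.int64)
        self.alive: list[bool] = [False]
        self.roots: list[int] = []  # sorted alive root ids
        self._roots_cache: np.ndarray | None = None
        self.unassigned = self.h * self.w
        self.offsets = _window_offsets(self.cp.th_o)
        self.std3 = _local_std(self.img)
        self.log: list[tuple] = []
        self.delta_thetas: list[float] = []

        M = self.qp.swarm_size
        self.L = self.qp.resolved_L(self.h, self.w)
        self.budget = self.qp.resolved_max_iter()
        pos01 = self.rng.random((M, 2))
        self.positions = pos01 * np.array([self.h - 1, self.w - 1], dtype=np.float64)
        pfit = np.array([self._fitness(p) for p in self.positions])
        gi = int(np.argmax(pfit))
        self.swarm = SwarmState(
            positions=self.positions,
            personal_bests=self.positions.copy(),
            personal_fitness=pfit,
            global_best=self.positions[gi].copy(),
            global_fitness=float(pfit[gi]),
        )

    # -- cluster bookkeeping ------------------------------------------------

    def _root_arrays(self):
        ids = self._roots_cache
        if ids is None:
            ids = self._roots_cache = np.array(self.roots, dtype=np.int64)
        size = self.size[ids].astype(np.float64)
        means = self.gsum[ids] / size
        cr = self.rsum[ids] / size
        cc = self.csum[ids] / size
        return ids, means, cr, cc, size

    def _new_cluster(self, pixels: list[tuple[int, int]]) -> int:
        cid = self.uf.add()
        if cid >= self._cap:
            self._cap *= 2
            for name in ("gsum", "rsum", "csum", "size"):
                old = getattr(self, name)
                grown = np.zeros(self._cap, dtype=old.dtype)
                grown[: old.size] = old
                setattr(self, name, grown)
        self.alive.append(True)
        self.roots.append(cid)
        self._roots_cache = None
        for p in pixels:
            self._assign(p, cid)
        return cid

    def _assign(self, p: tuple[int, int], root: int) -> None:
        self.labels[p] = root
        self.gsum[root] += self.img[p]
        self.rsum[root] += p[0]
        self.csum[root] += p[1]
        self.size[root] += 1
        self.unassigned -= 1

    def _merge(self, a: int, b: int) -> int:
        root = self.uf.union(a, b)
        child = b if root == a else a
        self.gsum[root] += self.gsum[child]
        self.rsum[root] += self.rsum[child]
        self.csum[root] += self.csum[child]
        self.size[root] += self.size[child]
        self.alive[child] = False
        self.roots.remove(child)
        self._roots_cache = None
        return root

    def _label_at(self, p: tuple[int, int]) -> int:
        raw = int(self.labels[p])
        return self.uf.find(raw) if raw else 0

    def _window_roots(self, p: tuple[int, int]) -> set[int]:
        """Roots of clusters owning a pixel within th_o of p."""
        ys = self.offsets[:, 0] + p[0]
        xs = self.offsets[:, 1] + p[1]
        ok = (ys >= 0) & (ys < self.h) & (xs >= 0) & (xs < self.w)
        raw = self.labels[ys[ok], xs[ok]]
        return {self.uf.find(int(x)) for x in raw[raw > 0]}

    def _mean(self, root: int) -> float:
        return self.gsum[root] / self.size[root]

    def _centroid(self, root: int) -> tuple[float, float]:
        n = self.size[root]
        return (self.rsum[root] / n, self.csum[root] / n)

    # -- swarm helpers ------------------------------------------------------

    def _fitness(self, pos: np.ndarray) -> float:
        p = position_to_pixel((pos[0], pos[1]), self.h, self.w)
        if not self.roots:
            return -float(self.std3[p])
        _, means, cr, cc, _ = self._root_arrays()
        d2 = (cr - pos[0]) ** 2 + (cc - pos[1]) ** 2
        k = int(np.argmin(d2))
        return -abs(float(self.img[p]) - float(means[k]))

    def _update_bests(self, i: int) -> None:
        f = self._fitness(self.positions[i])
        if f > self.swarm.personal_fitness[i]:
            self.swarm.personal_fitness[i] = f
            self.swarm.personal_bests[i] = self.positions[i]
        if f > self.swarm.global_fitness:
            self.swarm.global_fitness = f
            self.swarm.global_best = self.positions[i].copy()

    def _unit_open(self) -> float:
        """A draw in (0, 1] (the update rules take log(1/u))."""
        return 1.0 - float(self.rng.random())

    def _step5(self, i: int) -> None:
        """Standard QPSO move of particle i (per axis)."""
        mb = self.swarm.mean_best
        new = np.empty(2)
        for ax in range(2):
            phi1 = float(self.rng.random())
            phi2 = float(self.rng.random())
            if phi1 + phi2 > 0:
                p_ax = local_attractor(
                    float(self.swarm.personal_bests[i, ax]),
                    float(self.swarm.global_best[ax]),
                    phi1,
                    phi2,
                )
            else:  # measure-zero guard
                p_ax = 0.5 * (self.swarm.personal_bests[i, ax] + self.swarm.global_best[ax])
            mu = self._unit_open()
            new[ax] = qpso_update(
                float(self.positions[i, ax]), p_ax, float(mb[ax]), self.qp.alpha, mu
            )
        self.positions[i, 0] = min(max(new[0], 0.0), self.h - 1)
        self.positions[i, 1] = min(max(new[1], 0.0), self.w - 1)
        self._update_bests(i)

    def _dtheta(self, a: int, b: int) -> float:
        if self.wp.delta_theta_policy == "fixed":
            return self.wp.delta_theta_fixed
        ra, ca_ = self._centroid(a)
        rb, cb_ = self._centroid(b)
        ea = embed_point(ra, ca_, self.h, self.w, self.wp.disc_radius)
        eb = embed_point(rb, cb_, self.h, self.w, self.wp.disc_radius)
        return angular_separation(ea, eb)

    def _step6(self, i: int, a: int, b: int) -> None:
        """Wormhole move of seed particle i toward cluster b's centroid,
        then the merge test between clusters a and b."""
        dtheta = self._dtheta(a, b)
        self.delta_thetas.append(dtheta)
        mb = self.swarm.mean_best
        cb = self._centroid(b)
        new = np.empty(2)
        for ax in range(2):
            new[ax] = wormhole_update(
                float(self.positions[i, ax]), cb[ax], float(mb[ax]), dtheta, self.wp.zeta
            )
        self.positions[i, 0] = min(max(new[0], 0.0), self.h - 1)
        self.positions[i, 1] = min(max(new[1], 0.0), self.w - 1)
        self._update_bests(i)

        if self._wormhole_ok(a, b, dtheta):
            ea = embed_point(*self._centroid(a), self.h, self.w, self.wp.disc_radius)
            eb = embed_point(*self._centroid(b), self.h, self.w, self.wp.disc_radius)
            x = hyperbolic_path_length(ea.r, eb.r, dtheta, self.wp.zeta)
            prob = connection_probability(x, self.wp)
            root = self._merge(a, b)
            self.log.append(("wormhole", a, b, dtheta, x, prob, root))

    def _wormhole_ok(self, a: int, b: int, dtheta: float) -> bool:
        if self.size[a] < 2 or self.size[b] < 2:
            return False
        if abs(self._mean(a) - self._mean(b)) > self.cp.th_f:
            return False
        (ra, ca_), (rb, cb_) = self._centroid(a), self._centroid(b)
        if math.hypot(ra - rb, ca_ - cb_) <= self.cp.th_o:
            return False
        ea = embed_point(ra, ca_, self.h, self.w, self.wp.disc_radius)
        eb = embed_point(rb, cb_, self.h, self.w, self.wp.disc_radius)
        x = hyperbolic_path_length(ea.r, eb.r, dtheta, self.wp.zeta)
        return connection_probability(x, self.wp) >= self.wp.connect_prob_min

    # -- meetings -----------------------------------------------------------

    def _nearest_entity(self, i: int):
        """Spatially nearest entity: ('particle', j) or ('cluster', root)."""
        pos = self.positions[i]
        d2p = np.sum((self.positions - pos) ** 2, axis=1)
        d2p[i] = np.inf
        jp = int(np.argmin(d2p))
        best_p = d2p[jp]
        if self.roots:
            ids, _, cr, cc, _ = self._root_arrays()
            d2c = (cr - pos[0]) ** 2 + (cc - pos[1]) ** 2
            kc = int(np.argmin(d2c))
            if d2c[kc] < best_p:
                return ("cluster", int(ids[kc]))
        return ("particle", jp)

    def _most_similar_foreign(self, a: int):
        """Wormhole partner for cluster a: the foreign cluster closest in
        the *hidden* similarity metric (smallest |mean difference|).

        Spatial neighbors (centroid distance <= th_o) are not candidates —
        they belong to the entanglement domain, and a wormhole "is not in
        the neighborhood" by definition. Ties prefer the farther cluster
        (wormholes link long-distance nodes), then the lower id.
        """
        if len(self.roots) < 2:
            return None
        ids, means, cr, cc, _ = self._root_arrays()
        ra, ca_ = self._centroid(a)
        dist = np.hypot(cr - ra, cc - ca_)
        sel = (ids != a) & (dist > self.cp.th_o)
        if not sel.any():
            return None
        ids, means, dist = ids[sel], means[sel], dist[sel]
        diff = np.abs(means - self._mean(a))
        order = np.lexsort((ids, -dist, diff))
        return int(ids[order[0]])

    def _best_admitting(self, p: tuple[int, int]):
        """The reachable cluster (a member within th_o) whose running mean
        best matches p's gray, if any admits p under the Eq-19 test."""
        g = float(self.img[p])
        best = None
        for root in sorted(self._window_roots(p)):
            df = abs(g - self._mean(root))
            if df <= self.cp.th_f and (best is None or df < best[0]):
                best = (df, root)
        return None if best is None else best[1]

    # -- main loop ----------------------------------------------------------

    def run(self) -> SegmentationResult:
        M = self.qp.swarm_size
        step = 0
        while step < self.budget and self.unassigned > 0:
            i = step % M
            step += 1
            pix = position_to_pixel(tuple(self.positions[i]), self.h, self.w)
            lab = self._label_at(pix)
            if lab == 0:
                self._pixel_meeting(i, pix)
            else:
                # seed particle
                b = self._most_similar_foreign(lab) if self.config.wormhole_enabled else None
                if b is None:
                    self._step5(i)
                else:
                    self._step6(i, lab, b)
                # stagnation escape: a seed particle whose move did not
                # leave its pixel has nothing further to contribute there
                # and is re-dispersed uniformly
                if position_to_pixel(tuple(self.positions[i]), self.h, self.w) == pix:
                    self.positions[i] = self.rng.random(2) * np.array(
                        [self.h - 1, self.w - 1]
                    )
                    self._update_bests(i)
        return self._finalize(step)

    def _pixel_meeting(self, i: int, pix: tuple[int, int]) -> None:
        """Steps 2-3 for a pixel particle; the particle always moves on
        afterwards (one position update per loop step)."""
        kind, ent = self._nearest_entity(i)
        if kind == "particle":
            pj = position_to_pixel(tuple(self.positions[ent]), self.h, self.w)
            if self._label_at(pj) == 0 and pixels_entangled(pix, pj, self.image, self.cp):
                pixels = [pix] if pix == pj else [pix, pj]
                cid = self._new_cluster(pixels)
                self.log.append(("entangle", pix, pj, cid))
                self._step5(i)
                return
        root = self._best_admitting(pix)
        if root is not None:
            self.log.append(("absorb", pix, root, self._mean(root)))
            self._assign(pix, root)
        else:
            cid = self._new_cluster([pix])
            self.log.append(("found", pix, cid))
        self._step5(i)

    # -- finalization -------------------------------------------------------

    def _resolved_labels(self) -> np.ndarray:
        lut = np.array([self.uf.find(x) for x in range(len(self.uf.parent))], dtype=np.int32)
        return lut[self.labels]

    def _attach_leftovers(self) -> None:
        """Attach unassigned pixels to the cluster minimizing
        (gray difference, centroid distance, id), lexicographically."""
        if self.unassigned == 0:
            return
        if not self.roots:
            # degenerate: the budget ran out before any cluster formed
            ys, xs = np.nonzero(self.labels == 0)
            cid = self._new_cluster([])
            for y, x in zip(ys, xs):
                self._assign((int(y), int(x)), cid)
                self.log.append(("leftover", (int(y), int(x)), cid))
            return
        labels_res = self._resolved_labels()
        un = labels_res == 0
        ys, xs = np.nonzero(un)
        g = self.img[ys, xs]
        best_df = np.full(ys.shape, np.inf)
        best_dd = np.full(ys.shape, np.inf)
        best_id = np.full(ys.shape, np.iinfo(np.int64).max)
        ids, means, cr, cc, _ = self._root_arrays()
        for k in range(len(ids)):
            df = np.abs(g - means[k])
            dd = np.hypot(ys - cr[k], xs - cc[k])
            better = (df < best_df) | (
                (df == best_df) & ((dd < best_dd) | ((dd == best_dd) & (ids[k] < best_id)))
            )
            best_df[better] = df[better]
            best_dd[better] = dd[better]
            best_id[better] = ids[k]
        for y, x, cid in zip(ys, xs, best_id):
            self._assign((int(y), int(x)), int(cid))
            self.log.append(("leftover", (int(y), int(x)), int(cid)))

    def _coalesce(self) -> None:
        """Union clusters that are gray-similar (pre-merge means) and whose
        members come within th_o of each other — the cluster-level closure
        of the pixel entanglement test."""
        labels_res = self._resolved_labels()
        premeans = {r: self._mean(r) for r in self.roots}
        nmax = len(self.uf.parent)
        pair_codes: set[int] = set()
        half = self.offsets[
            (self.offsets[:, 0] > 0)
            | ((self.offsets[:, 0] == 0) & (self.offsets[:, 1] > 0))
        ]
        for dy, dx in half:
            a = labels_res[
                max(0, -dy) : self.h - max(0, dy), max(0, -dx) : self.w - max(0, dx)
            ]
            b = labels_res[
                max(0, dy) : self.h + min(0, dy) or self.h,
                max(0, dx) : self.w + min(0, dx) or self.w,
            ]
            diff = a != b
            lo = np.minimum(a[diff], b[diff]).astype(np.int64)
            hi = np.maximum(a[diff], b[diff]).astype(np.int64)
            pair_codes.update(np.unique(lo * nmax + hi).tolist())
        for code in sorted(pair_codes):
            a, b = divmod(code, nmax)
            if a == 0:
                continue
            if abs(premeans[a] - premeans[b]) <= self.cp.th_f:
                ra, rb = self.uf.find(a), self.uf.find(b)
                if ra != rb:
                    self._merge(ra, rb)
                    self.log.append(("coalesce", a, b))

    def _foreground(self, labels: np.ndarray, clusters: list[Cluster]) -> np.ndarray:
        means = np.array([c.mean_gray for c in clusters])
        if len(clusters) < 2 or np.ptp(means) < 1e-9:
            return np.zeros_like(labels, dtype=bool)
        thr = threshold_otsu(means[labels - 1])
        if self.config.polarity == "bright-object":
            side = [c for c in clusters if c.mean_gray > thr]
        else:
            side = [c for c in clusters if c.mean_gray < thr]
        if not side:
            return np.zeros_like(labels, dtype=bool)
        obj = min(side, key=lambda c: (-c.size, c.id))
        return labels == obj.id

    def _finalize(self, steps: int) -> SegmentationResult:
        self._attach_leftovers()
        self._coalesce()
        labels_res = self._resolved_labels()
        roots = sorted(self.roots)
        remap = np.zeros(len(self.uf.parent), dtype=np.int32)
        for new_id, root in enumerate(roots, start=1):
            remap[root] = new_id
        final = remap[labels_res]
        clusters = []
        for new_id, root in enumerate(roots, start=1):
            ys, xs = np.nonzero(final == new_id)
            members = {(int(y), int(x)) for y, x in zip(ys, xs)}
            clusters.append(Cluster.from_members(new_id, members, self.image))
        fg = self._foreground(final, clusters)
        return SegmentationResult(
            labels=final,
            foreground=fg,
            clusters=clusters,
            iterations_used=steps,
            rng_seed=self.config.seed,
            log=self.log,
            delta_thetas=self.delta_thetas,
        )


def qwpso_segment(image: np.ndarray, config: QwpsoConfig | None = None) -> SegmentationResult:
    """Segment a grayscale image with the QWPSO algorithm.

    Deterministic given (image, config, seed). With
    ``config.wormhole_enabled = False`` the run is bitwise identical to
    :func:`qwpso.qpso.qpso_segment` under the same parameters.
    """
    return _Engine(image, config or QwpsoConfig()).run()
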