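"""Shared domain types for the segmentation engines.

Conventions used throughout the package:

* images are 2-D ``numpy.uint8`` arrays indexed ``(row, col)``, row
  increasing downward, 0-based;
* particle positions are continuous ``(row, col)`` coordinates; whenever a
  gray value is needed the position is rounded half-up to the nearest pixel
  and clipped to the image bounds;
* intensities stay on the native 0–255 scale (no normalization), so the
  gray-similarity threshold ``th_f`` is an 8-bit gray difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class InputError(ValueError):
    """An input file is missing, unreadable or malformed."""


class PixelPos(NamedTuple):
    """Continuous image-plane coordinate in (row, col) order."""

    row: float
    col: float


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (2.5 -> 3)."""
    return int(np.floor(x + 0.5))


def clip_position(pos: tuple[float, float], height: int, width: int) -> tuple[float, float]:
    """Clip a continuous (row, col) position to the image bounds."""
    r = min(max(pos[0], 0.0), float(height - 1))
    c = min(max(pos[1], 0.0), float(width - 1))
    return (r, c)


def position_to_pixel(pos: tuple[float, float], height: int, width: int) -> tuple[int, int]:
    """Continuous position -> integer pixel (round half-up, then clip)."""
    r = min(max(round_half_up(pos[0]), 0), height - 1)
    c = min(max(round_half_up(pos[1]), 0), width - 1)
    return (r, c)


@dataclass(frozen=True)
class ClusterParams:
    """Entanglement thresholds of the clustering tests.

    th_f : float
        Maximum gray-value difference (8-bit intensity units) for two
        pixels, or a pixel and a cluster's running mean, to be entangled.
    th_o : float
        Maximum Euclidean pixel distance for entanglement / absorption;
        also the neighborhood radius below which two clusters count as
        adjacent rather than wormhole candidates.
    """

    th_f: float = 10.0
    th_o: float = 3.0

    def __post_init__(self) -> None:
        if self.th_f < 0:
            raise ParameterError(f"th_f must be >= 0, got {self.th_f}")
        if self.th_o < 0:
            raise ParameterError(f"th_o must be >= 0, got {self.th_o}")


@dataclass
class Cluster:
    """A labeled set of pixels with its running statistics.

    ``kind`` is ``"seed"`` for clusters with at least two members (eligible
    for wormhole linking) and ``"pixel-group"`` for singletons.
    """

    id: int
    members: set[tuple[int, int]]
    mean_gray: float
    centroid: PixelPos
    kind: str = "seed"

    @staticmethod
    def from_members(cid: int, members: set[tuple[int, int]], image: np.ndarray) -> "Cluster":
        if not members:
            raise ParameterError("a cluster must have at least one member")
        coords = np.array(sorted(members), dtype=np.int64)
        grays = image[coords[:, 0], coords[:, 1]].astype(np.float64)
        centroid = PixelPos(float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        kind = "seed" if len(members) >= 2 else "pixel-group"
        return Cluster(cid, set(members), float(grays.mean()), centroid, kind)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SegmentationResult:
    """Output of a segmentation run.

    labels : (H, W) int32 array; 0 would mean unassigned, but on return
        every pixel carries a cluster id >= 1.
    foreground : (H, W) bool array, the binary object mask.
    clusters : final cluster inventory (consecutive ids, matching labels).
    iterations_used : number of particle updates consumed.
    rng_seed : the seed that reproduces the run.
    log : chronological event log; tuples whose first element names the
        event (``"entangle"``, ``"absorb"``, ``"found"``, ``"wormhole"``,
        ``"leftover"``). Used to audit cluster admission rules.
    delta_thetas : every angular separation fed to the wormhole update.
    """

    labels: np.ndarray
    foreground: np.ndarray
    clusters: list[Cluster]
    iterations_used: int
    rng_seed: int
    log: list[tuple] = field(default_factory=list)
    delta_thetas: list[float] = field(default_factory=list)

    def cluster_by_id(self, cid: int) -> Cluster:
        for c in self.clusters:
            if c.id == cid:
                return c
        raise KeyError(cid)
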