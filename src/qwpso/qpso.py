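"""Quantum-behaved PSO primitives and the QPSO baseline segmenter.

Particles in QPSO do not carry a velocity: each one is re-sampled around a
local attractor built from its personal best and the global best, with a
Laplace-shaped spread derived from a Delta potential well,

    Q(y) = (1/L) exp(-2|y|/L),        y = x - p,

which Monte-Carlo inversion turns into the sampling rule

    X = P ± (L/2) ln(1/u),            u ~ U(0, 1].

The iterative update additionally scales the spread by the distance to the
mean-best position ``Mbest`` through the contraction–expansion coefficient
``alpha``:

    x(t+1) = P -/+ alpha * |Mbest - x(t)| * ln(1/mu),

with the ``-`` branch taken when ``mu > 0.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import ClusterParams, ParameterError, SegmentationResult


@dataclass(frozen=True)
class QpsoParams:
    """QPSO swarm parameters.

    alpha : contraction–expansion coefficient (dimensionless, > 0).
    L : characteristic length of the potential well in pixels; ``None``
        resolves to 0.1 * max(height, width) at run time.
    swarm_size : number of roaming particles M.
    max_iter : budget of particle position updates; ``None`` resolves to
        200 * swarm_size.
    """

    alpha: float = 0.75
    L: Optional[float] = None
    swarm_size: int = 40
    max_iter: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.L is not None and self.L <= 0:
            raise ParameterError(f"L must be > 0, got {self.L}")
        if self.swarm_size < 2:
            raise ParameterError(f"swarm_size must be >= 2, got {self.swarm_size}")
        if self.max_iter is not None and self.max_iter < 1:
            raise ParameterError(f"max_iter must be >= 1, got {self.max_iter}")

    def resolved_L(self, height: int, width: int) -> float:
        return self.L if self.L is not None else 0.1 * max(height, width)

    def resolved_max_iter(self) -> int:
        return self.max_iter if self.max_iter is not None else 200 * self.swarm_size


@dataclass
class SwarmState:
    """Positions, bests and fitness of the particle swarm.

    All arrays have one row per particle; coordinates are continuous
    (row, col) pairs.
    """

    positions: np.ndarray
    personal_bests: np.ndarray
    personal_fitness: np.ndarray
    global_best: np.ndarray
    global_fitness: float

    @property
    def mean_best(self) -> np.ndarray:
        """Coordinate-wise mean of the personal bests (Mbest)."""
        return self.personal_bests.mean(axis=0)


def delta_well_density(y: float, L: float) -> float:
    """Probability density of the Delta-well position offset y."""
    if L <= 0:
        raise ParameterError(f"L must be > 0, got {L}")
    return (1.0 / L) * math.exp(-2.0 * abs(y) / L)


def sample_well_position(p: float, L: float, u: float, sign: int) -> float:
    """Draw a position around attractor p: ``p + sign*(L/2)*ln(1/u)``."""
    if u <= 0:
        raise ParameterError(f"u must be in (0, 1], got {u}")
    if L <= 0:
        raise ParameterError(f"L must be > 0, got {L}")
    return p + sign * (L / 2.0) * math.log(1.0 / u)


def local_attractor(p_id: float, p_gd: float, phi1: float, phi2: float) -> float:
    """Convex combination (phi1*p_id + phi2*p_gd)/(phi1 + phi2)."""
    if phi1 + phi2 <= 0:
        raise ParameterError("phi1 + phi2 must be > 0")
    return (phi1 * p_id + phi2 * p_gd) / (phi1 + phi2)


def mean_best(personal_bests: Sequence) -> np.ndarray:
    """Coordinate-wise arithmetic mean of the personal best positions."""
    arr = np.asarray(personal_bests, dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("personal_bests must be non-empty")
    return arr.mean(axis=0)


def qpso_update(x_t: float, p: float, mbest: float, alpha: float, mu: float) -> float:
    """One-axis QPSO move: attractor minus/plus the scaled log spread.

    The ``-`` branch applies when ``mu > 0.5``, the ``+`` branch otherwise.
    """
    if mu <= 0:
        raise ParameterError(f"mu must be in (0, 1], got {mu}")
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    spread = alpha * abs(mbest - x_t) * math.log(1.0 / mu)
    return p - spread if mu > 0.5 else p + spread


def qpso_segment(
    image: np.ndarray,
    qp: QpsoParams | None = None,
    cp: ClusterParams | None = None,
    seed: int = 0,
    polarity: str = "bright-object",
) -> SegmentationResult:
    """Segment an image with the plain QPSO engine (no wormhole branch).

    Runs the shared clustering loop with wormhole handling disabled:
    seed–seed meetings fall through to the standard QPSO move. The result
    is bit-reproducible for a fixed seed.
    """
    from .engine import QwpsoConfig, qwpso_segment
    from .wormhole import WormholeParams

    config = QwpsoConfig(
        qpso=qp or QpsoParams(),
        cluster=cp or ClusterParams(),
        wormhole=WormholeParams(),
        polarity=polarity,
        seed=seed,
        wormhole_enabled=False,
    )
    return qwpso_segment(image, config)
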