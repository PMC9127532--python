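"""The hyperbolic wormhole path measure.

Clusters are embedded as nodes of a hyperbolic disc of radius ``R``
(node count ``N = c * exp(R/2)``, uniform angular density ``1/(2*pi)``,
radial density ``rho(r) ~ exp(-zeta*r/2)``). The path length between two
nodes at radii r, r' separated by the angle ``dtheta`` (degrees) is

    x = r + r' + (2/zeta) * ln(dtheta / 2),

and two nodes connect with probability ``exp(zeta*(x - R)/2)``, clamped
to 1. Admissible angular separations span (0, 57.32] degrees — 57.32 being
the printed value of 360/(2*pi) — which is 15.9% of the full 0–360 range
swept by the QPSO random draw; this range restriction is the source of
the method's efficiency argument.

The position update along a wormhole mirrors the QPSO update with the
random log term replaced by the deterministic ``ln(dtheta/2)``:

    x(t+1) = P(t) -/+ (2/zeta) * |Mbest - x(t)| * ln(dtheta/2),

the ``-`` branch for ``dtheta > 2`` and the ``+`` branch for
``dtheta <= 2``. The logarithm is kept signed (no absolute value), so for
``dtheta <= 2`` the added term is non-positive, mirroring the behaviour of
the QPSO ``mu <= 0.5`` branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import Cluster, ParameterError

# Admissible angular-separation range in degrees: the printed value of
# 360/(2*pi) as the hard upper clamp, with a small positive floor so the
# logarithm stays finite when two embedded nodes coincide angularly.
ANGLE_MAX_DEG = 57.32
ANGLE_MIN_DEG = 0.01


@dataclass(frozen=True)
class WormholeParams:
    """Parameters of the hyperbolic wormhole measure.

    zeta : distance coefficient scaling the logarithmic term (> 0).
    disc_radius : hyperbolic disc radius R.
    avg_degree_c : the constant c in N = c * exp(R/2); kept for parameter
        semantics (no network is simulated).
    delta_theta_policy : "measured" computes the angle per cluster pair
        from the disc embedding; "fixed" uses ``delta_theta_fixed``.
    delta_theta_fixed : degrees, used when the policy is "fixed".
    connect_prob_min : minimum connection probability for a wormhole to
        be accepted between two seed clusters.
    """

    zeta: float = 1.0
    disc_radius: float = 10.0
    avg_degree_c: float = 1.0
    delta_theta_policy: str = "measured"
    delta_theta_fixed: float = 0.6
    connect_prob_min: float = 0.5

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ParameterError(f"zeta must be > 0, got {self.zeta}")
        if self.disc_radius <= 0:
            raise ParameterError(f"disc_radius must be > 0, got {self.disc_radius}")
        if self.delta_theta_policy not in ("fixed", "measured"):
            raise ParameterError(
                f"delta_theta_policy must be 'fixed' or 'measured', got {self.delta_theta_policy!r}"
            )
        if self.delta_theta_policy == "fixed" and not (0 < self.delta_theta_fixed < ANGLE_MAX_DEG):
            raise ParameterError(
                f"delta_theta_fixed must be in (0, {ANGLE_MAX_DEG}), got {self.delta_theta_fixed}"
            )
        if not (0 < self.connect_prob_min <= 1):
            raise ParameterError(
                f"connect_prob_min must be in (0, 1], got {self.connect_prob_min}"
            )


@dataclass(frozen=True)
class DiscCoords:
    """Polar coordinates of a cluster embedded in the hyperbolic disc."""

    r: float
    theta: float  # degrees in [0, 360)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ParameterError(f"r must be >= 0, got {self.r}")
        if not (0 <= self.theta < 360):
            raise ParameterError(f"theta must be in [0, 360), got {self.theta}")


def hyperbolic_path_length(r: float, r_prime: float, delta_theta: float, zeta: float) -> float:
    """Wormhole path length ``x = r + r' + (2/zeta) * ln(delta_theta/2)``."""
    if delta_theta <= 0:
        raise ParameterError(f"delta_theta must be > 0, got {delta_theta}")
    if zeta <= 0:
        raise ParameterError(f"zeta must be > 0, got {zeta}")
    return r + r_prime + (2.0 / zeta) * math.log(delta_theta / 2.0)


def node_radial_density(r: float, zeta: float) -> float:
    """Approximate radial node density ``exp(-zeta * r / 2)``."""
    if zeta <= 0:
        raise ParameterError(f"zeta must be > 0, got {zeta}")
    return math.exp(-zeta * r / 2.0)


def connection_probability(x: float, params: WormholeParams) -> float:
    """Connection probability ``exp(zeta*(x - R)/2)``, clamped to 1.

    The raw exponential exceeds 1 for x > R; it is clamped so the value is
    a valid probability. Longer hidden paths thus connect more readily —
    the wormhole links long-distance nodes.
    """
    return min(1.0, math.exp(params.zeta * (x - params.disc_radius) / 2.0))


def wormhole_position(p_id: float, delta_theta: float, zeta: float, sign: int) -> float:
    """Wormhole position sample ``p +/- (2/zeta) * ln(delta_theta/2)``."""
    if delta_theta <= 0:
        raise ParameterError(f"delta_theta must be > 0, got {delta_theta}")
    if zeta <= 0:
        raise ParameterError(f"zeta must be > 0, got {zeta}")
    return p_id + sign * (2.0 / zeta) * math.log(delta_theta / 2.0)


def wormhole_update(
    x_t: float, p_t: float, mbest: float, delta_theta: float, zeta: float
) -> float:
    """One-axis wormhole move; branch on the angle between nodes.

    ``-`` for delta_theta > 2, ``+`` for delta_theta <= 2; the logarithm
    stays signed, so both branches coincide at delta_theta = 2.
    """
    if delta_theta <= 0:
        raise ParameterError(f"delta_theta must be > 0, got {delta_theta}")
    if zeta <= 0:
        raise ParameterError(f"zeta must be > 0, got {zeta}")
    term = (2.0 / zeta) * abs(mbest - x_t) * math.log(delta_theta / 2.0)
    return p_t - term if delta_theta > 2.0 else p_t + term


def embed_point(
    row: float, col: float, height: int, width: int, disc_radius: float
) -> DiscCoords:
    """Embed an image-plane point into the hyperbolic disc.

    The radial coordinate is the Euclidean distance from the image centre
    ((h-1)/2, (w-1)/2), normalized by the distance from the centre to the
    continuous image corner (hypot(h/2, w/2)) and scaled to ``disc_radius``;
    the angle is the polar angle about the centre, degrees in [0, 360).
    """
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    dy, dx = row - cy, col - cx
    half_diag = math.hypot(height / 2.0, width / 2.0)
    r = math.hypot(dy, dx) / half_diag * disc_radius
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    return DiscCoords(min(r, disc_radius), theta)


def disc_embed(cluster: Cluster, image, disc_radius: float = 10.0) -> DiscCoords:
    """Embed a cluster (by its centroid) into the hyperbolic disc."""
    h, w = image.shape[:2]
    return embed_point(cluster.centroid.row, cluster.centroid.col, h, w, disc_radius)


def angular_separation(a: DiscCoords, b: DiscCoords) -> float:
    """Minimal angular difference folded to [0, 180], clamped to the
    admissible wormhole range [0.01, 57.32] degrees."""
    d = abs(a.theta - b.theta) % 360.0
    if d > 180.0:
        d = 360.0 - d
    return min(max(d, ANGLE_MIN_DEG), ANGLE_MAX_DEG)
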