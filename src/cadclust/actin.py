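"""Projected actin meshwork: construction from a concentration budget,
obstruction tests, binding-region bookkeeping and stochastic turnover.

The 3D cortex is reduced to line segments on each membrane: the projection of
a filament tilted by ``phi`` from the membrane normal across an effective
slab of thickness ``h_actin`` has length ``L_F = h_actin * tan(phi)``.  The
whole segment obstructs cadherin movement on its own plane; a contiguous
sub-segment (a fixed fraction of the length, at a random offset) additionally
binds cadherins.

Filaments are rigid and static between turnover events.  Turnover removes
each filament independently with per-step probability ``1 - exp(-dt/tau)``
and replaces it immediately with a freshly sampled one, conserving the
filament count (and hence the actin concentration); bonds on removed
filaments are released.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import LineSegment2, PeriodicDomain, _segments_cross
from .state import ActinSegment, KineticParams, SystemState, NONE

__all__ = [
    "ActinNetworkSpec",
    "SUBUNITS_PER_UM",
    "projected_length",
    "segment_count",
    "build_network",
    "obstructs",
    "turnover",
    "filament_pieces",
]

#: F-actin subunits per micron of filament (2.7 nm helical rise per subunit).
SUBUNITS_PER_UM = 370.0

AVOGADRO = 6.02214076e23

#: pieces used for minimal-image tests never exceed this fraction of the
#: smaller domain dimension, keeping segment-level geometry unambiguous.
MAX_PIECE_FRACTION = 0.45


@dataclass
class ActinNetworkSpec:
    """Declarative description of one plane's meshwork."""

    phi_deg: Optional[float] = None  # tilt from the membrane normal
    h_actin: float = 100.0  # nm
    L_F: Optional[float] = None  # nm; explicit value wins over phi
    actin_conc: float = 0.0  # uM
    binding_fraction: float = 0.2
    lifetime: float = math.inf  # s
    per_plane: bool = True

    def resolved_length(self) -> float:
        """Explicit L_F wins; otherwise L_F = h_actin * tan(phi)."""
        if self.L_F is not None:
            return float(self.L_F)
        if self.phi_deg is None:
            raise ValueError("either L_F or phi_deg must be given")
        return projected_length(self.h_actin, self.phi_deg)

    def back_computed_phi_deg(self) -> Optional[float]:
        if self.h_actin <= 0:
            return None
        return math.degrees(math.atan(self.resolved_length() / self.h_actin))


def projected_length(h_actin: float, phi_deg: float) -> float:
    """Projected filament length ``h_actin * tan(phi)`` (nm)."""
    if not 0.0 <= phi_deg < 90.0:
        raise ValueError(f"phi must be in [0, 90) degrees, got {phi_deg}")
    return float(h_actin * math.tan(math.radians(phi_deg)))


def segment_count(
    actin_conc_uM: float, dom: PeriodicDomain, h_actin_nm: float, L_F_nm: float
) -> int:
    """Number of filaments per plane holding the actin concentration fixed.

    The concentration is referred to the slab volume ``area * h_actin``; the
    subunit budget is converted to total filament length at 370 subunits per
    micron and divided into segments of length ``L_F``.
    """
    if L_F_nm <= 0:
        raise ValueError(f"L_F must be > 0, got {L_F_nm}")
    if actin_conc_uM <= 0:
        return 0
    volume_l = dom.area_um2 * 1e-12 * h_actin_nm * 1e-9 * 1e3  # um^2 -> m^2, nm -> m, m^3 -> L
    n_subunits = actin_conc_uM * 1e-6 * AVOGADRO * volume_l
    total_len_nm = n_subunits / SUBUNITS_PER_UM * 1e3
    return int(round(total_len_nm / L_F_nm))


def build_network(
    dom: PeriodicDomain,
    n: int,
    L_F: float,
    binding_fraction: float,
    plane: int,
    rng: np.random.Generator,
    now: float = 0.0,
    id_offset: int = 0,
) -> List[ActinSegment]:
    """``n`` filaments with uniform anchors and directions; each carries a
    contiguous binding sub-segment of relative length ``binding_fraction`` at
    a uniform random offset."""
    if n < 0:
        raise ValueError(f"filament count must be >= 0, got {n}")
    segs: List[ActinSegment] = []
    for k in range(n):
        anchor = np.array([rng.uniform(0, dom.width), rng.uniform(0, dom.height)])
        angle = rng.uniform(0.0, 2 * math.pi)
        b0 = rng.uniform(0.0, 1.0 - binding_fraction) if binding_fraction < 1.0 else 0.0
        segs.append(
            ActinSegment(
                id=id_offset + k,
                plane=plane,
                anchor=anchor,
                angle=angle,
                length=L_F,
                binding_start=b0,
                binding_len=binding_fraction,
                birth_time=now,
            )
        )
    return segs


def filament_pieces(
    seg: ActinSegment, dom: PeriodicDomain
) -> List[Tuple[float, float, float, float]]:
    """Split a filament into collinear pieces short enough for unambiguous
    minimal-image tests.  Returns ``(ax, ay, dx, dy)`` anchor+delta tuples."""
    max_len = MAX_PIECE_FRACTION * dom.min_dim
    k = max(1, int(math.ceil(seg.length / max_len)))
    ux, uy = math.cos(seg.angle), math.sin(seg.angle)
    step = seg.length / k
    out = []
    for j in range(k):
        out.append(
            (
                float(seg.anchor[0] + j * step * ux),
                float(seg.anchor[1] + j * step * uy),
                step * ux,
                step * uy,
            )
        )
    return out


def obstructs(
    path: LineSegment2,
    plane: int,
    network: Sequence[ActinSegment] | SystemState,
    dom: PeriodicDomain,
) -> bool:
    """True iff the move path crosses any filament of the given plane's
    network.  The whole filament obstructs, not just its binding region;
    filaments of the other plane are transparent."""
    if isinstance(network, SystemState):
        segs = [network.filament(k) for k in range(network.n_filaments)]
    else:
        segs = list(network)
    pdx = path.bx - path.ax
    pdy = path.by - path.ay
    for seg in segs:
        if seg.plane != plane:
            continue
        for ax, ay, dx, dy in filament_pieces(seg, dom):
            if _segments_cross(path.ax, path.ay, pdx, pdy, ax, ay, dx, dy, dom.width, dom.height):
                return True
    return False


def turnover(
    state: SystemState,
    rng: np.random.Generator,
    dt: Optional[float] = None,
) -> Tuple[List[int], List[int]]:
    """One turnover sweep over the state's filaments (in place).

    Each filament is removed with probability ``1 - exp(-dt/lifetime)`` and
    immediately replaced by a freshly sampled filament on the same plane
    (same length and binding fraction), conserving the count.  Returns the
    removed filament indices and the monomer ids whose cadherin-actin bonds
    were released.
    """
    params = state.params
    if dt is None:
        dt = params.dt
    tau = params.actin_lifetime
    if not tau > 0:
        raise ValueError(f"actin_lifetime must be > 0, got {tau}")
    if math.isinf(tau) or state.n_filaments == 0:
        return [], []
    p_remove = -math.expm1(-dt / tau)
    removed: List[int] = []
    released: List[int] = []
    dom = state.domain
    for k in range(state.n_filaments):
        if rng.uniform() >= p_remove:
            continue
        removed.append(k)
        bound = np.nonzero(state.actin_bond == k)[0]
        for i in bound:
            state.actin_bond[i] = NONE
            released.append(int(i))
        bf = state.fil_b1[k] - state.fil_b0[k]
        state.fil_anchor[k, 0] = rng.uniform(0, dom.width)
        state.fil_anchor[k, 1] = rng.uniform(0, dom.height)
        state.fil_angle[k] = rng.uniform(0.0, 2 * math.pi)
        b0 = rng.uniform(0.0, 1.0 - bf) if bf < 1.0 else 0.0
        state.fil_b0[k] = b0
        state.fil_b1[k] = b0 + bf
        state.fil_birth[k] = state.time
    return removed, released
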