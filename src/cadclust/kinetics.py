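"""Bond eligibility, per-step reaction probabilities and post-binding
structural adjustment.

The model separates each binding reaction into a diffusion part (partners
must satisfy a distance and an orientation criterion) and an intrinsic part
(a per-step Bernoulli trial with probability ``1 - exp(-k * dt)``).  Trans
bonds join the column-axis centres of monomers on opposite membranes and the
pair is aligned coaxially with a 90 degree packing offset; cis bonds join a
donor site to an acceptor site on the same membrane and the pair is packed
into a linear chain (centres one diameter apart, orientations synchronised).

Angle criterion: by default (``angle_convention="packing"``) the angular
deviation is measured from each bond type's ideal packing (90 degrees offset
for trans, parallel axes for cis), so the post-binding adjustment is always a
small correction.  ``"raw"`` applies the cutoff to the bare orientation
difference for both bond kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .geometry import PeriodicDomain, _mi1
from .state import CadherinMonomer, KineticParams, acceptor_site, donor_site

__all__ = [
    "BondProposal",
    "association_probability",
    "dissociation_probability",
    "circular_diff",
    "trans_eligible",
    "cis_eligible",
    "cad_actin_eligible",
    "apply_trans_geometry",
    "apply_cis_geometry",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class BondProposal:
    kind: str  # "trans" | "cis" | "cad_actin"
    first: int  # monomer id (donor side for cis)
    second: int  # monomer id, or actin segment id for cad_actin
    distance: float  # nm
    angle_dev_deg: float  # deviation used for the cutoff test


def association_probability(k_ass: float, dt: float) -> float:
    """Per-step intrinsic association probability ``1 - exp(-k_ass * dt)``."""
    if k_ass < 0:
        raise ValueError(f"k_ass must be >= 0, got {k_ass}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return float(-np.expm1(-k_ass * dt))


def dissociation_probability(k_dis: float, dt: float) -> float:
    """Per-step dissociation probability, same exponential form."""
    if k_dis < 0:
        raise ValueError(f"k_dis must be >= 0, got {k_dis}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return float(-np.expm1(-k_dis * dt))


# ---------------------------------------------------------------------------
# numba angle primitives (shared with the simulation kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _circ(x):
    """Map an angle difference to (-pi, pi]."""
    r = math.pi - (math.pi - x) % TWO_PI
    if r <= -math.pi:
        r += TWO_PI
    return r


@njit(cache=True)
def _trans_dev(ti, tj, theta_trans, raw):
    """Angular deviation for a trans pair.

    Packing mode: distance of the orientation difference from +/- the trans
    packing angle (the sign is not fixed, so the test is symmetric in the
    two monomers).  Raw mode: |orientation difference|.
    """
    d = _circ(tj - ti)
    if raw:
        return abs(d)
    dev_p = abs(_circ(d - theta_trans))
    dev_m = abs(_circ(d + theta_trans))
    return min(dev_p, dev_m)


@njit(cache=True)
def _cis_dev(ti, tj):
    """Angular deviation for a cis pair: ideal packing is parallel axes, so
    this is simply |orientation difference| (identical in raw mode)."""
    return abs(_circ(tj - ti))


def circular_diff(a: float, b: float = 0.0) -> float:
    """Signed circular difference ``a - b`` mapped to ``(-pi, pi]`` (radians)."""
    return float(_circ(a - b))


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def _mi_dist(p, q, dom: PeriodicDomain) -> float:
    return math.hypot(
        _mi1(float(q[0]) - float(p[0]), dom.width),
        _mi1(float(q[1]) - float(p[1]), dom.height),
    )


def trans_eligible(
    a: CadherinMonomer, b: CadherinMonomer, params: KineticParams, dom: PeriodicDomain
) -> Optional[BondProposal]:
    """Trans bond proposal, or None.

    Requires opposite planes, both trans slots free, minimal-image distance
    between the column axes below ``dc_trans`` (the trans site sits on the
    column axis), and angular deviation below the cutoff angle.
    """
    if a.plane == b.plane:
        return None
    if a.trans_partner is not None or b.trans_partner is not None:
        return None
    d = _mi_dist(a.center, b.center, dom)
    if d >= params.dc_trans:
        return None
    dev = _trans_dev(
        a.theta,
        b.theta,
        math.radians(params.theta_trans_deg),
        params.angle_convention == "raw",
    )
    if dev >= math.radians(params.a_c_deg):
        return None
    return BondProposal("trans", a.id, b.id, d, math.degrees(dev))


def cis_eligible(
    a: CadherinMonomer, b: CadherinMonomer, params: KineticParams, dom: PeriodicDomain
) -> Optional[BondProposal]:
    """Cis bond proposal ``a``'s donor -> ``b``'s acceptor, or None."""
    if a.plane != b.plane or a.id == b.id:
        return None
    if a.cis_donor_partner is not None or b.cis_acceptor_partner is not None:
        return None
    d = _mi_dist(donor_site(a, params), acceptor_site(b, params), dom)
    if d >= params.dc_cis:
        return None
    dev = _cis_dev(a.theta, b.theta)
    if dev >= math.radians(params.a_c_deg):
        return None
    return BondProposal("cis", a.id, b.id, d, math.degrees(dev))


def cad_actin_eligible(
    m: CadherinMonomer, s, params: KineticParams, dom: PeriodicDomain
) -> Optional[BondProposal]:
    """Cadherin-actin bond proposal, or None.

    No angular condition: the actin-binding site sits inside the membrane.
    Only the binding sub-segment of the filament counts; the obstruction
    region does not bind.
    """
    from .geometry import point_segment_distance

    if m.plane != s.plane or m.actin_bond is not None:
        return None
    bseg = s.binding_segment
    if bseg is None:
        return None
    d = point_segment_distance(m.center, bseg, dom)
    if d >= params.dc_cad_actin:
        return None
    return BondProposal("cad_actin", m.id, s.id, d, 0.0)


# ---------------------------------------------------------------------------
# post-binding structural adjustment (pure record-level forms)
# ---------------------------------------------------------------------------


def apply_trans_geometry(
    a: CadherinMonomer, b: CadherinMonomer, dom: PeriodicDomain, params: KineticParams
) -> Tuple[CadherinMonomer, CadherinMonomer]:
    """Align a freshly trans-bonded pair: both centres at the minimal-image
    midpoint (wrapped) and ``theta_b = theta_a +/- theta_trans`` (the branch
    nearest b's current orientation)."""
    from .geometry import min_image_disp, wrap

    d = min_image_disp(a.center, b.center, dom)
    mid = wrap(np.asarray(a.center, dtype=float) + 0.5 * d, dom)
    tt = math.radians(params.theta_trans_deg)
    delta = _circ(b.theta - a.theta)
    if abs(_circ(delta - tt)) <= abs(_circ(delta + tt)):
        tb = (a.theta + tt) % TWO_PI
    else:
        tb = (a.theta - tt) % TWO_PI
    a2 = CadherinMonomer(a.id, a.plane, mid.copy(), a.theta, b.id,
                         a.cis_donor_partner, a.cis_acceptor_partner, a.actin_bond)
    b2 = CadherinMonomer(b.id, b.plane, mid.copy(), tb, a.id,
                         b.cis_donor_partner, b.cis_acceptor_partner, b.actin_bond)
    return a2, b2


def apply_cis_geometry(
    a: CadherinMonomer,
    b: CadherinMonomer,
    dom: PeriodicDomain,
    params: KineticParams,
    mobility: Tuple[bool, bool] = (True, True),
) -> Tuple[CadherinMonomer, CadherinMonomer]:
    """Pack a freshly cis-bonded pair (a's donor -> b's acceptor) into the
    chain arrangement: centres ``2*r_cad`` apart along the donor direction,
    orientations synchronised.

    ``mobility`` flags which of (a, b) may be relocated.  Among the movable
    monomers the one with fewer existing bonds moves; ties move the acceptor
    side (b).  If neither may move the bond is recorded without relocation.
    """
    from .geometry import min_image_disp, wrap

    sep = 2.0 * params.r_cad
    ma, mb = mobility
    mover: Optional[str] = None
    if ma and mb:
        mover = "a" if a.n_bonds() < b.n_bonds() else "b"
    elif ma:
        mover = "a"
    elif mb:
        mover = "b"

    ca = np.asarray(a.center, dtype=float)
    cb = np.asarray(b.center, dtype=float)
    ta, tb = a.theta, b.theta
    if mover == "b":
        u = np.array([math.cos(ta), math.sin(ta)])
        delta = min_image_disp(cb, ca, dom) + sep * u
        cb = wrap(cb + delta, dom)
        tb = ta
    elif mover == "a":
        u = np.array([math.cos(tb), math.sin(tb)])
        delta = min_image_disp(ca, cb, dom) - sep * u
        ca = wrap(ca + delta, dom)
        ta = tb
    a2 = CadherinMonomer(a.id, a.plane, ca, ta, a.trans_partner,
                         b.id, a.cis_acceptor_partner, a.actin_bond)
    b2 = CadherinMonomer(b.id, b.plane, cb, tb, b.trans_partner,
                         b.cis_donor_partner, a.id, b.actin_bond)
    return a2, b2
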