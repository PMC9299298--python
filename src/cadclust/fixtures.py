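"""Hand-built states used by the test suite and the ``fixtures`` CLI verb.

These are synthetic constructions, not simulation output: a closed triangle
of obstructing filaments around a single monomer (corralling), a small
bonded arrangement exercising every bond slot, and an obstructing square box
with a single gap (escape-time experiments).
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np

from .geometry import PeriodicDomain
from .state import ActinSegment, CadherinMonomer, KineticParams, SystemState


def triangle_corral(
    domain: Optional[PeriodicDomain] = None,
    params: Optional[KineticParams] = None,
    center=(500.0, 500.0),
    radius: float = 60.0,
) -> SystemState:
    """One free monomer at the centroid of a closed obstructing triangle.

    The triangle sides overlap at the corners so there is no gap; with
    obstruction enabled the monomer can never leave.
    """
    domain = domain or PeriodicDomain(1000.0, 1000.0)
    params = params or KineticParams(actin_conc=0.0, kass_trans=0.0, kass_cis=0.0,
                                     kass_cad_actin=0.0, binding_fraction=0.0)
    cx, cy = center
    verts = [
        (cx + radius * math.cos(a), cy + radius * math.sin(a))
        for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3)
    ]
    segs: List[ActinSegment] = []
    for k in range(3):
        ax, ay = verts[k]
        bx, by = verts[(k + 1) % 3]
        segs.append(
            ActinSegment(
                id=k, plane=0,
                anchor=np.array([ax, ay]),
                angle=math.atan2(by - ay, bx - ax),
                length=math.hypot(bx - ax, by - ay),
                binding_start=0.0, binding_len=0.0,
            )
        )
    mono = [CadherinMonomer(id=0, plane=0, center=np.array([cx, cy]), theta=0.0)]
    return SystemState.from_monomers(mono, domain, params, actin=segs)


def square_box_with_gap(
    side: float,
    gap: float,
    domain: Optional[PeriodicDomain] = None,
    params: Optional[KineticParams] = None,
    center=(500.0, 500.0),
) -> SystemState:
    """One monomer inside an obstructing square with one gap of width ``gap``
    centred on the top edge; used for mesh escape-time experiments."""
    domain = domain or PeriodicDomain(1000.0, 1000.0)
    params = params or KineticParams(actin_conc=0.0, kass_trans=0.0, kass_cis=0.0,
                                     kass_cad_actin=0.0, binding_fraction=0.0)
    cx, cy = center
    h = side / 2.0
    corners = [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
    edges = []
    # bottom, right, left: full; top split around the gap
    edges.append((corners[0], corners[1]))
    edges.append((corners[1], corners[2]))
    edges.append((corners[3], corners[0]))
    edges.append((corners[2], (cx + gap / 2.0, cy + h)))
    edges.append(((cx - gap / 2.0, cy + h), corners[3]))
    segs = []
    for k, ((ax, ay), (bx, by)) in enumerate(edges):
        L = math.hypot(bx - ax, by - ay)
        if L <= 0:
            continue
        segs.append(
            ActinSegment(
                id=len(segs), plane=0,
                anchor=np.array([ax, ay]),
                angle=math.atan2(by - ay, bx - ax),
                length=L, binding_start=0.0, binding_len=0.0,
            )
        )
    mono = [CadherinMonomer(id=0, plane=0, center=np.array([cx, cy]), theta=0.0)]
    return SystemState.from_monomers(mono, domain, params, actin=segs)


def three_monomer_state(
    domain: Optional[PeriodicDomain] = None,
    params: Optional[KineticParams] = None,
) -> SystemState:
    """A trans dimer plus a cis-bonded neighbour, exercising every slot kind."""
    domain = domain or PeriodicDomain(1000.0, 1000.0)
    params = params or KineticParams()
    mono = [
        CadherinMonomer(id=0, plane=0, center=np.array([100.0, 100.0]), theta=0.0,
                        trans_partner=1, cis_donor_partner=2),
        CadherinMonomer(id=1, plane=1, center=np.array([100.0, 100.0]),
                        theta=math.pi / 2, trans_partner=0),
        CadherinMonomer(id=2, plane=0, center=np.array([105.0, 100.0]), theta=0.0,
                        cis_acceptor_partner=0),
    ]
    return SystemState.from_monomers(mono, domain, params)
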