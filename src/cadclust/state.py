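"""Domain types and composite simulation state.

The state is kept as struct-of-arrays (positions, orientations, bond slots)
so the numba step kernel can operate on it directly; :class:`CadherinMonomer`
and :class:`ActinSegment` are lightweight record views used by tests, fixture
construction and the snapshot writers.

Units: nm, s, degrees in parameter surfaces; monomer orientations are stored
internally in radians in ``[0, 2*pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .geometry import LineSegment2, PeriodicDomain, _wrap1

__all__ = [
    "KineticParams",
    "CadherinMonomer",
    "ActinSegment",
    "SystemState",
    "donor_site",
    "acceptor_site",
    "init_state",
]

NONE = -1  # empty bond slot in the integer arrays


@dataclass
class KineticParams:
    """Every rate, cutoff and geometric constant of the model.

    ``D_rot=None`` resolves to the value giving a 10 degree angular step per
    time step, i.e. ``(10deg in rad)^2 / (2*dt)``.
    """

    dt: float = 1e-5  # s
    D: float = 1e5  # nm^2/s (0.1 um^2/s); step length = sqrt(4*D*dt)
    D_rot: Optional[float] = None  # rad^2/s; per-step angle = sqrt(2*D_rot*dt)
    r_cad: float = 2.5  # nm, monomer radius
    dc_trans: float = 1.5  # nm, trans cutoff distance
    dc_cis: float = 3.0  # nm, cis cutoff distance (between donor/acceptor sites)
    dc_cad_actin: float = 3.5  # nm, cadherin-actin cutoff (~F-actin radius)
    a_c_deg: float = 30.0  # cutoff angle
    theta_trans_deg: float = 90.0  # trans packing angle
    theta_cis_deg: float = 180.0  # cis packing angle (linear chain; parallel axes)
    kass_trans: float = 1e5  # 1/s
    kdis_trans: float = 1.0  # 1/s
    kass_cis: float = 1e5  # 1/s
    kdis_cis: float = 1e3  # 1/s
    kass_cad_actin: float = 1e5  # 1/s
    kdis_cad_actin: float = 0.1  # 1/s
    h_actin: float = 100.0  # nm, effective-region thickness
    L_F: float = 200.0  # nm, projected filament length
    actin_conc: float = 0.0  # uM
    cad_density: float = 1200.0  # per um^2, per plane
    binding_fraction: float = 0.2  # fraction of filament length that binds
    actin_lifetime: float = math.inf  # s; inf disables turnover
    angle_convention: str = "packing"  # "packing": deviation from ideal; "raw": |dtheta|

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.D_rot is None:
            self.D_rot = math.radians(10.0) ** 2 / (2.0 * self.dt)
        self.validate()

    def validate(self) -> None:
        positives = ["dt"]
        nonneg = [
            "D", "D_rot", "r_cad", "dc_trans", "dc_cis", "dc_cad_actin",
            "kass_trans", "kdis_trans", "kass_cis", "kdis_cis",
            "kass_cad_actin", "kdis_cad_actin", "h_actin", "L_F",
            "actin_conc", "cad_density", "actin_lifetime",
        ]
        for name in positives:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.binding_fraction <= 1.0:
            raise ValueError(f"binding_fraction must be in [0, 1], got {self.binding_fraction}")
        if not 0.0 < self.a_c_deg < 180.0:
            raise ValueError(f"a_c_deg must be in (0, 180), got {self.a_c_deg}")
        if self.angle_convention not in ("packing", "raw"):
            raise ValueError(f"angle_convention must be 'packing' or 'raw', got {self.angle_convention!r}")
        if self.step_length >= self.dc_cis and self.D > 0:
            raise ValueError(
                f"sampling inadequate: step sqrt(4*D*dt)={self.step_length:.3g} nm "
                f"must stay below dc_cis={self.dc_cis} nm"
            )

    @property
    def step_length(self) -> float:
        """Per-step displacement magnitude sqrt(4*D*dt), nm."""
        return math.sqrt(4.0 * self.D * self.dt)

    @property
    def rot_step(self) -> float:
        """Per-step rotation magnitude sqrt(2*D_rot*dt), rad."""
        return math.sqrt(2.0 * self.D_rot * self.dt)

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass
class CadherinMonomer:
    """Record view of one coarse-grained cadherin."""

    id: int
    plane: int
    center: np.ndarray
    theta: float  # rad, in [0, 2*pi)
    trans_partner: Optional[int] = None
    cis_donor_partner: Optional[int] = None  # partner bound at *this* monomer's donor site
    cis_acceptor_partner: Optional[int] = None
    actin_bond: Optional[int] = None

    def n_bonds(self) -> int:
        return sum(
            x is not None
            for x in (
                self.trans_partner,
                self.cis_donor_partner,
                self.cis_acceptor_partner,
                self.actin_bond,
            )
        )


@dataclass
class ActinSegment:
    """A projected F-actin filament: rigid line segment with a contiguous
    binding sub-segment (fractions of its length) and a birth time for
    turnover."""

    id: int
    plane: int
    anchor: np.ndarray  # nm
    angle: float  # rad
    length: float  # nm
    binding_start: float  # fraction in [0, 1]
    binding_len: float  # fraction; binding_start + binding_len <= 1
    birth_time: float = 0.0

    @property
    def geometry(self) -> LineSegment2:
        return LineSegment2(
            float(self.anchor[0]),
            float(self.anchor[1]),
            float(self.anchor[0] + self.length * math.cos(self.angle)),
            float(self.anchor[1] + self.length * math.sin(self.angle)),
        )

    @property
    def binding_segment(self) -> Optional[LineSegment2]:
        if self.binding_len <= 0:
            return None
        ux, uy = math.cos(self.angle), math.sin(self.angle)
        s0 = self.binding_start * self.length
        s1 = (self.binding_start + self.binding_len) * self.length
        return LineSegment2(
            float(self.anchor[0] + s0 * ux),
            float(self.anchor[1] + s0 * uy),
            float(self.anchor[0] + s1 * ux),
            float(self.anchor[1] + s1 * uy),
        )


def _opt(v: int) -> Optional[int]:
    return None if v == NONE else int(v)


@dataclass
class SystemState:
    """Full simulation state (both membranes coexist in one 2D domain).

    Monomer arrays are indexed by monomer id; filament arrays by filament id.
    ``unwrapped`` accumulates every raw (minimal-image) position change so
    trajectories can be analysed without boundary artefacts.
    """

    domain: PeriodicDomain
    params: KineticParams
    pos: np.ndarray  # (N, 2) float64, wrapped
    theta: np.ndarray  # (N,) float64, rad
    plane: np.ndarray  # (N,) int64, 0 or 1
    trans: np.ndarray  # (N,) int64, partner id or -1
    cis_donor: np.ndarray  # (N,) int64; partner bound at my donor site
    cis_acceptor: np.ndarray  # (N,) int64
    actin_bond: np.ndarray  # (N,) int64, filament id or -1
    fil_anchor: np.ndarray  # (M, 2) float64
    fil_angle: np.ndarray  # (M,) float64
    fil_len: np.ndarray  # (M,) float64
    fil_b0: np.ndarray  # (M,) float64, binding start fraction
    fil_b1: np.ndarray  # (M,) float64, binding end fraction
    fil_birth: np.ndarray  # (M,) float64
    fil_plane: np.ndarray  # (M,) int64
    time: float = 0.0
    unwrapped: np.ndarray = field(default=None)  # (N, 2) cumulative displacement

    def __post_init__(self) -> None:
        if self.unwrapped is None:
            self.unwrapped = np.zeros_like(self.pos)

    # -- sizes ------------------------------------------------------------
    @property
    def n_monomers(self) -> int:
        return self.pos.shape[0]

    @property
    def n_filaments(self) -> int:
        return self.fil_anchor.shape[0]

    # -- record views -----------------------------------------------------
    def monomer(self, i: int) -> CadherinMonomer:
        return CadherinMonomer(
            id=i,
            plane=int(self.plane[i]),
            center=self.pos[i].copy(),
            theta=float(self.theta[i]),
            trans_partner=_opt(self.trans[i]),
            cis_donor_partner=_opt(self.cis_donor[i]),
            cis_acceptor_partner=_opt(self.cis_acceptor[i]),
            actin_bond=_opt(self.actin_bond[i]),
        )

    def monomers(self) -> Iterator[CadherinMonomer]:
        for i in range(self.n_monomers):
            yield self.monomer(i)

    def filament(self, k: int) -> ActinSegment:
        return ActinSegment(
            id=k,
            plane=int(self.fil_plane[k]),
            anchor=self.fil_anchor[k].copy(),
            angle=float(self.fil_angle[k]),
            length=float(self.fil_len[k]),
            binding_start=float(self.fil_b0[k]),
            binding_len=float(self.fil_b1[k] - self.fil_b0[k]),
            birth_time=float(self.fil_birth[k]),
        )

    def filaments(self) -> Iterator[ActinSegment]:
        for k in range(self.n_filaments):
            yield self.filament(k)

    def copy(self) -> "SystemState":
        return SystemState(
            domain=self.domain,
            params=self.params,
            pos=self.pos.copy(),
            theta=self.theta.copy(),
            plane=self.plane.copy(),
            trans=self.trans.copy(),
            cis_donor=self.cis_donor.copy(),
            cis_acceptor=self.cis_acceptor.copy(),
            actin_bond=self.actin_bond.copy(),
            fil_anchor=self.fil_anchor.copy(),
            fil_angle=self.fil_angle.copy(),
            fil_len=self.fil_len.copy(),
            fil_b0=self.fil_b0.copy(),
            fil_b1=self.fil_b1.copy(),
            fil_birth=self.fil_birth.copy(),
            fil_plane=self.fil_plane.copy(),
            time=self.time,
            unwrapped=self.unwrapped.copy(),
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def empty(cls, domain: PeriodicDomain, params: KineticParams, n: int = 0) -> "SystemState":
        return cls(
            domain=domain,
            params=params,
            pos=np.zeros((n, 2)),
            theta=np.zeros(n),
            plane=np.zeros(n, dtype=np.int64),
            trans=np.full(n, NONE, dtype=np.int64),
            cis_donor=np.full(n, NONE, dtype=np.int64),
            cis_acceptor=np.full(n, NONE, dtype=np.int64),
            actin_bond=np.full(n, NONE, dtype=np.int64),
            fil_anchor=np.zeros((0, 2)),
            fil_angle=np.zeros(0),
            fil_len=np.zeros(0),
            fil_b0=np.zeros(0),
            fil_b1=np.zeros(0),
            fil_birth=np.zeros(0),
            fil_plane=np.zeros(0, dtype=np.int64),
        )

    @classmethod
    def from_monomers(
        cls,
        monomers: Sequence[CadherinMonomer],
        domain: PeriodicDomain,
        params: KineticParams,
        actin: Sequence[ActinSegment] = (),
        time: float = 0.0,
    ) -> "SystemState":
        """Build a state from explicit records (hand-built fixtures)."""
        n = len(monomers)
        st = cls.empty(domain, params, n)
        for idx, m in enumerate(monomers):
            if m.id != idx:
                raise ValueError(f"monomer ids must be 0..n-1 in order; got {m.id} at {idx}")
            st.pos[idx] = [
                _wrap1(float(m.center[0]), domain.width),
                _wrap1(float(m.center[1]), domain.height),
            ]
            st.theta[idx] = float(m.theta) % (2 * math.pi)
            st.plane[idx] = m.plane
            st.trans[idx] = NONE if m.trans_partner is None else m.trans_partner
            st.cis_donor[idx] = NONE if m.cis_donor_partner is None else m.cis_donor_partner
            st.cis_acceptor[idx] = (
                NONE if m.cis_acceptor_partner is None else m.cis_acceptor_partner
            )
            st.actin_bond[idx] = NONE if m.actin_bond is None else m.actin_bond
        if actin:
            st.fil_anchor = np.array([[s.anchor[0], s.anchor[1]] for s in actin], dtype=float)
            st.fil_angle = np.array([s.angle for s in actin], dtype=float)
            st.fil_len = np.array([s.length for s in actin], dtype=float)
            st.fil_b0 = np.array([s.binding_start for s in actin], dtype=float)
            st.fil_b1 = np.array(
                [s.binding_start + s.binding_len for s in actin], dtype=float
            )
            st.fil_birth = np.array([s.birth_time for s in actin], dtype=float)
            st.fil_plane = np.array([s.plane for s in actin], dtype=np.int64)
        st.time = time
        st.audit()
        return st

    # -- bookkeeping ------------------------------------------------------
    def n_trans_bonds(self) -> int:
        return int(np.count_nonzero(self.trans >= 0) // 2)

    def n_cis_bonds(self) -> int:
        return int(np.count_nonzero(self.cis_donor >= 0))

    def n_actin_bonds(self) -> int:
        return int(np.count_nonzero(self.actin_bond >= 0))

    def audit(self, check_geometry: bool = False, tol: float = 1e-9) -> None:
        """Verify structural invariants; raise AssertionError on violation.

        ``check_geometry`` additionally verifies coaxial trans pairs (used by
        tests on freshly adjusted bonds; dense lattices formed between
        immobilised members keep their pre-bond offsets, see methods note).
        """
        n = self.n_monomers
        for i in range(n):
            if not (0.0 <= self.pos[i, 0] < self.domain.width):
                raise AssertionError(f"monomer {i} x out of domain: {self.pos[i, 0]}")
            if not (0.0 <= self.pos[i, 1] < self.domain.height):
                raise AssertionError(f"monomer {i} y out of domain: {self.pos[i, 1]}")
            j = self.trans[i]
            if j >= 0:
                if j == i or self.trans[j] != i:
                    raise AssertionError(f"trans bond asymmetry at {i}<->{j}")
                if self.plane[i] == self.plane[j]:
                    raise AssertionError(f"trans bond within one plane at {i}<->{j}")
            j = self.cis_donor[i]
            if j >= 0:
                if j == i or self.cis_acceptor[j] != i:
                    raise AssertionError(f"cis bond asymmetry at donor {i} -> {j}")
                if self.plane[i] != self.plane[j]:
                    raise AssertionError(f"cis bond across planes at {i} -> {j}")
            j = self.cis_acceptor[i]
            if j >= 0 and self.cis_donor[j] != i:
                raise AssertionError(f"cis bond asymmetry at acceptor {i} <- {j}")
            k = self.actin_bond[i]
            if k >= 0:
                if k >= self.n_filaments:
                    raise AssertionError(f"monomer {i} bound to missing filament {k}")
                if self.fil_plane[k] != self.plane[i]:
                    raise AssertionError(f"monomer {i} bound to filament on other plane")
        if check_geometry:
            from .geometry import min_image_disp

            for i in range(n):
                j = self.trans[i]
                if j > i:
                    d = min_image_disp(self.pos[i], self.pos[j], self.domain)
                    if math.hypot(d[0], d[1]) > tol:
                        raise AssertionError(
                            f"trans pair {i}<->{j} not coaxial: offset {d}"
                        )


# ---------------------------------------------------------------------------
# site geometry
# ---------------------------------------------------------------------------


def donor_site(m: CadherinMonomer, params: KineticParams) -> np.ndarray:
    """Cis donor site: ``center + r_cad * (cos theta, sin theta)``."""
    return np.array(
        [
            m.center[0] + params.r_cad * math.cos(m.theta),
            m.center[1] + params.r_cad * math.sin(m.theta),
        ]
    )


def acceptor_site(m: CadherinMonomer, params: KineticParams) -> np.ndarray:
    """Cis acceptor (receptor) site, diametrically opposite the donor."""
    return np.array(
        [
            m.center[0] - params.r_cad * math.cos(m.theta),
            m.center[1] - params.r_cad * math.sin(m.theta),
        ]
    )


def init_state(
    domain: PeriodicDomain,
    params: KineticParams,
    rng: np.random.Generator | int,
) -> SystemState:
    """Random initial state: ``round(cad_density * area)`` monomers per plane,
    uniform positions and orientations, no bonds, actin networks built per
    plane from the concentration budget.  Fully determined by the seed."""
    from . import actin as actin_mod

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_per_plane = int(round(params.cad_density * domain.area_um2))
    n = 2 * n_per_plane
    st = SystemState.empty(domain, params, n)
    st.pos[:, 0] = rng.uniform(0.0, domain.width, n)
    st.pos[:, 1] = rng.uniform(0.0, domain.height, n)
    st.theta[:] = rng.uniform(0.0, 2 * math.pi, n)
    st.plane[n_per_plane:] = 1
    if params.actin_conc > 0 and params.L_F > 0:
        n_fil = actin_mod.segment_count(params.actin_conc, domain, params.h_actin, params.L_F)
        segs = []
        for plane in (0, 1):
            segs.extend(
                actin_mod.build_network(
                    domain,
                    n_fil,
                    params.L_F,
                    params.binding_fraction,
                    plane,
                    rng,
                    now=0.0,
                    id_offset=len(segs),
                )
            )
        if segs:
            st.fil_anchor = np.array([[s.anchor[0], s.anchor[1]] for s in segs])
            st.fil_angle = np.array([s.angle for s in segs])
            st.fil_len = np.array([s.length for s in segs])
            st.fil_b0 = np.array([s.binding_start for s in segs])
            st.fil_b1 = np.array([s.binding_start + s.binding_len for s in segs])
            st.fil_birth = np.array([s.birth_time for s in segs])
            st.fil_plane = np.array([s.plane for s in segs], dtype=np.int64)
    return st
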