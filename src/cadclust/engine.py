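"""Per-step update loop and run orchestration.

Each step executes, in order: actin turnover, diffusion of mobile units with
obstruction rejection, rotation, dissociation trials for every bond, and
association over eligible proposals (with post-binding geometry adjustment),
then advances the clock by ``dt``.  A *mobile unit* is a lone monomer or a
trans dimer none of whose members carries a cis or actin bond; cis-bonded and
actin-tethered cadherins are immobilised (actin-tethered ones still rotate).

The hot loop lives in :mod:`cadclust._kernels`; :func:`advance` and
:func:`step` drive it on a :class:`~cadclust.state.SystemState`, and
:func:`run` executes a full scheduled simulation with snapshot and
trajectory recording.  Runs are deterministic in the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import _kernels
from .actin import MAX_PIECE_FRACTION, obstructs
from .geometry import LineSegment2, PeriodicDomain, wrap
from .state import KineticParams, SystemState, init_state
from .kinetics import association_probability, dissociation_probability

__all__ = ["MobileUnit", "RunSchedule", "RunResult", "mobile_units",
           "diffusion_move", "rotation_move", "step", "advance", "run"]

EVENT_NAMES = [
    "trans_created", "trans_broken", "cis_created", "cis_broken",
    "actin_created", "actin_broken", "trans_pair_steps",
    "moves_accepted", "moves_rejected", "turnover_removals", "proposals",
]


@dataclass(frozen=True)
class MobileUnit:
    member_ids: tuple
    kind: str  # "monomer" | "trans_dimer"


@dataclass
class RunSchedule:
    duration: float  # s
    snapshot_interval: float  # s
    trajectory_interval: float  # s
    seed: int = 0

    def steps(self, dt: float):
        n_total = int(round(self.duration / dt))
        snap = max(1, int(round(self.snapshot_interval / dt)))
        traj = max(1, int(round(self.trajectory_interval / dt)))
        if snap % traj != 0:
            raise ValueError(
                "snapshot_interval must be a multiple of trajectory_interval "
                f"(got {snap} vs {traj} steps)"
            )
        return n_total, snap, traj


def mobile_units(state: SystemState) -> tuple[List[MobileUnit], List[int]]:
    """Partition the monomers into mobile units and immobilised ids."""
    units: List[MobileUnit] = []
    immobile: List[int] = []
    seen = np.zeros(state.n_monomers, dtype=bool)

    def _anchored(i: int) -> bool:
        return (
            state.cis_donor[i] >= 0
            or state.cis_acceptor[i] >= 0
            or state.actin_bond[i] >= 0
        )

    for i in range(state.n_monomers):
        if seen[i]:
            continue
        j = int(state.trans[i])
        if j >= 0:
            seen[i] = seen[j] = True
            if _anchored(i) or _anchored(j):
                immobile.extend([i, j])
            else:
                units.append(MobileUnit((min(i, j), max(i, j)), "trans_dimer"))
        else:
            seen[i] = True
            if _anchored(i):
                immobile.append(i)
            else:
                units.append(MobileUnit((i,), "monomer"))
    return units, immobile


def diffusion_move(unit: MobileUnit, state: SystemState, rng: np.random.Generator) -> bool:
    """Propose one fixed-length step in a uniform random direction for the
    unit; reject (no movement) if any member's centre path crosses an
    obstructing filament on that member's plane.  Returns acceptance."""
    params = state.params
    L = params.step_length
    ang = rng.uniform(0.0, 2 * math.pi)
    ddx, ddy = L * math.cos(ang), L * math.sin(ang)
    if L > 0 and state.n_filaments > 0:
        segs = [state.filament(k) for k in range(state.n_filaments)]
        for i in unit.member_ids:
            path = LineSegment2(
                float(state.pos[i, 0]), float(state.pos[i, 1]),
                float(state.pos[i, 0] + ddx), float(state.pos[i, 1] + ddy),
            )
            if obstructs(path, int(state.plane[i]), segs, state.domain):
                return False
    for i in unit.member_ids:
        state.unwrapped[i, 0] += ddx
        state.unwrapped[i, 1] += ddy
        state.pos[i] = wrap(state.pos[i] + np.array([ddx, ddy]), state.domain)
    return True


def rotation_move(unit: MobileUnit, state: SystemState, rng: np.random.Generator) -> None:
    """Rotate a free monomer, actin-bound monomer, or cis-free trans dimer by
    the fixed angular step with random sign; cis-bonded monomers are locked."""
    for i in unit.member_ids:
        if state.cis_donor[i] >= 0 or state.cis_acceptor[i] >= 0:
            return
    dth = state.params.rot_step * (1.0 if rng.uniform() < 0.5 else -1.0)
    for i in unit.member_ids:
        state.theta[i] = (state.theta[i] + dth) % (2 * math.pi)


# ---------------------------------------------------------------------------
# kernel driving
# ---------------------------------------------------------------------------


def _chunk_layouts(state: SystemState) -> tuple[np.ndarray, np.ndarray]:
    """CSR offsets of obstruction and binding chunks per filament.

    Chunk lengths never exceed the corresponding grid cell size (nor the
    minimal-image bound); counts depend only on filament length and binding
    fraction, so the layout survives turnover."""
    M = state.n_filaments
    ob = np.zeros(M + 1, dtype=np.int64)
    bi = np.zeros(M + 1, dtype=np.int64)
    max_ob = min(_kernels.OB_CELL, MAX_PIECE_FRACTION * state.domain.min_dim)
    max_bi = min(_kernels.BI_CELL, MAX_PIECE_FRACTION * state.domain.min_dim)
    for f in range(M):
        ob[f + 1] = ob[f] + max(1, int(math.ceil(state.fil_len[f] / max_ob)))
        blen = (state.fil_b1[f] - state.fil_b0[f]) * state.fil_len[f]
        bi[f + 1] = bi[f] + (max(1, int(math.ceil(blen / max_bi))) if blen > 0 else 0)
    return ob, bi


def advance(
    state: SystemState,
    n_steps: int,
    seed: int,
    traj_every: int = 0,
    traj_out: Optional[np.ndarray] = None,
    counts: Optional[np.ndarray] = None,
    obstruction: bool = True,
    binding: bool = True,
    debug: bool = False,
) -> np.ndarray:
    """Advance the state ``n_steps`` in place; returns the event counts.

    ``debug=True`` runs the structural invariant audit afterwards and raises
    on any violation (slot symmetry, plane rules, wrapped positions)."""
    p = state.params
    if counts is None:
        counts = np.zeros(_kernels.N_COUNTS, dtype=np.int64)
    if traj_every > 0 and traj_out is None:
        traj_out = np.empty((n_steps // traj_every, state.n_monomers, 2))
    elif traj_every == 0:
        traj_out = np.empty((0, state.n_monomers, 2))
    tau = p.actin_lifetime
    p_turn = 0.0 if math.isinf(tau) else -math.expm1(-p.dt / tau)
    ob_start, bi_start = _chunk_layouts(state)
    state.time = _kernels.simulate_chunk(
        n_steps, int(seed) & 0x7FFFFFFF,
        state.pos, state.theta, state.plane, state.trans,
        state.cis_donor, state.cis_acceptor, state.actin_bond, state.unwrapped,
        state.fil_anchor[:, 0] if state.n_filaments else np.zeros(0),
        state.fil_anchor[:, 1] if state.n_filaments else np.zeros(0),
        state.fil_angle, state.fil_len, state.fil_b0, state.fil_b1,
        state.fil_birth, state.fil_plane,
        ob_start, bi_start,
        state.domain.width, state.domain.height, p.dt, p.step_length, p.rot_step,
        p.dc_trans, p.dc_cis, p.dc_cad_actin, p.r_cad,
        math.radians(p.a_c_deg), math.radians(p.theta_trans_deg),
        association_probability(p.kass_trans, p.dt),
        dissociation_probability(p.kdis_trans, p.dt),
        association_probability(p.kass_cis, p.dt),
        dissociation_probability(p.kdis_cis, p.dt),
        association_probability(p.kass_cad_actin, p.dt),
        dissociation_probability(p.kdis_cad_actin, p.dt),
        p_turn, obstruction, binding and p.binding_fraction > 0,
        p.angle_convention == "raw",
        state.time, traj_every, traj_out, counts,
    )
    if debug:
        state.audit()
    return counts


def step(state: SystemState, seed: int = 0, **kw) -> np.ndarray:
    """Advance exactly one time step (see :func:`advance`)."""
    return advance(state, 1, seed, **kw)


# ---------------------------------------------------------------------------
# scheduled runs
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Snapshots, sampled unwrapped trajectories and event totals of a run."""

    domain: PeriodicDomain
    params: KineticParams
    snapshots: List[SystemState]
    snapshot_times: np.ndarray
    traj: np.ndarray  # (S, N, 2) unwrapped positions, row 0 at t=0
    traj_times: np.ndarray
    events: dict
    final_state: SystemState = None
    converged_at: Optional[float] = None

    @property
    def n_monomers(self) -> int:
        return self.traj.shape[1]


def run(
    domain: PeriodicDomain,
    params: KineticParams,
    schedule: RunSchedule,
    state: Optional[SystemState] = None,
    obstruction: bool = True,
    binding: bool = True,
    keep_snapshots: bool = True,
    convergence_tol: Optional[float] = None,
    convergence_window: float = 10.0,
) -> RunResult:
    """Execute a scheduled simulation.

    The run seed determines both the initial state and the dynamics.  If a
    pre-built ``state`` is given (fixtures), only the dynamics consume the
    seed.  ``convergence_tol`` optionally stops the run early once the
    relative change of cumulative trans+cis binding events over a sliding
    window of ``convergence_window`` seconds falls below the tolerance.
    """
    ss = np.random.SeedSequence(schedule.seed)
    init_ss, dyn_ss = ss.spawn(2)
    if state is None:
        state = init_state(domain, params, np.random.default_rng(init_ss))
    n_total, snap_every, traj_every = schedule.steps(params.dt)
    n_chunks = max(1, math.ceil(n_total / snap_every)) if n_total > 0 else 0
    chunk_seeds = dyn_ss.generate_state(max(1, n_chunks), dtype=np.uint32)

    n_traj = n_total // traj_every
    traj = np.empty((n_traj + 1, state.n_monomers, 2))
    # kernel rows hold cumulative displacement; this offset makes them absolute
    offset = state.pos - state.unwrapped
    traj[0] = state.unwrapped + offset
    counts = np.zeros(_kernels.N_COUNTS, dtype=np.int64)
    snapshots = [state.copy()] if keep_snapshots else []
    snap_times = [state.time]

    history = []  # (time, cumulative trans+cis created) for convergence
    converged_at = None
    done = 0
    row = 1
    for c in range(n_chunks):
        k = min(snap_every, n_total - done)
        if k <= 0:
            break
        nrows = k // traj_every
        advance(
            state, k, int(chunk_seeds[c]),
            traj_every=traj_every,
            traj_out=traj[row : row + nrows],
            counts=counts,
            obstruction=obstruction,
            binding=binding,
        )
        row += nrows
        done += k
        if keep_snapshots:
            snapshots.append(state.copy())
        snap_times.append(state.time)
        if convergence_tol is not None:
            cum = counts[_kernels.C_TRANS_MADE] + counts[_kernels.C_CIS_MADE]
            history.append((state.time, cum))
            horizon = state.time - convergence_window
            past = [v for t, v in history if t <= horizon]
            if past and cum > 0:
                rel = (cum - past[-1]) / cum
                if rel < convergence_tol:
                    converged_at = state.time
                    break

    traj = traj[:row]
    # rows after t=0 hold cumulative displacements; make them absolute
    traj[1:] += offset[None, :, :]
    traj_times = np.arange(traj.shape[0]) * traj_every * params.dt
    events = {name: int(counts[i]) for i, name in enumerate(EVENT_NAMES)}
    return RunResult(
        domain=domain,
        params=params,
        snapshots=snapshots,
        snapshot_times=np.asarray(snap_times),
        traj=traj,
        traj_times=traj_times,
        events=events,
        final_state=state,
        converged_at=converged_at,
    )
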