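"""Measurements: cluster statistics, two-dimensional cis dissociation
constant, mean squared displacement and anomalous-diffusion exponents,
cluster lifetime tracking, and spatial patterning metrics.

A *cluster* is a connected component of the graph whose edges are the
current trans and cis bonds; a trans dimer therefore counts as a cluster of
size 2 and clusters may span both membranes.  Cluster centroids use the
circular-mean construction per coordinate so periodic wrap-around does not
bias them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np

from .geometry import PeriodicDomain
from .state import SystemState

__all__ = [
    "ClusterSnapshot",
    "ClusterTrack",
    "MsdCurve",
    "find_clusters",
    "max_cluster_size",
    "mean_cluster_size",
    "fraction_trans",
    "fraction_cis",
    "estimate_kd_cis",
    "msd",
    "msd_loglog_slope",
    "track_lifetimes",
    "nnd",
    "size_cv",
]


@dataclass
class ClusterSnapshot:
    time: float
    clusters: List[np.ndarray]  # member-id arrays; disjoint; union = all monomers
    centroids: np.ndarray  # (K, 2) minimal-image means

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)


@dataclass
class ClusterTrack:
    track_id: int
    birth: float
    death: Optional[float]  # None while open / right-censored
    sizes: List[int] = field(default_factory=list)
    censored: bool = False

    @property
    def lifetime(self) -> Optional[float]:
        return None if self.death is None else self.death - self.birth

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else 0.0


@dataclass
class MsdCurve:
    lags: np.ndarray  # s
    msd: np.ndarray  # nm^2
    n_contributing: np.ndarray


def _periodic_centroid(points: np.ndarray, dom: PeriodicDomain) -> np.ndarray:
    """Circular mean per coordinate, mapped back into the domain."""
    out = np.empty(2)
    for ax, L in ((0, dom.width), (1, dom.height)):
        ang = points[:, ax] * (2 * math.pi / L)
        m = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        out[ax] = (m * L / (2 * math.pi)) % L
    return out


def find_clusters(state: SystemState) -> ClusterSnapshot:
    """Connected components over the current trans and cis bonds
    (singletons included)."""
    n = state.n_monomers
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        j = int(state.trans[i])
        if j > i:
            g.add_edge(i, j)
        j = int(state.cis_donor[i])
        if j >= 0:
            g.add_edge(i, j)
    clusters = [np.array(sorted(c), dtype=int) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: int(c[0]))  # deterministic order
    cents = (
        np.vstack([_periodic_centroid(state.pos[c], state.domain) for c in clusters])
        if clusters
        else np.zeros((0, 2))
    )
    return ClusterSnapshot(time=state.time, clusters=clusters, centroids=cents)


def max_cluster_size(snap: ClusterSnapshot) -> int:
    sizes = snap.sizes
    return int(sizes.max()) if sizes.size else 0


def mean_cluster_size(snap: ClusterSnapshot, min_size: int = 5) -> float:
    """Mean size over clusters with at least ``min_size`` members ("more than
    4"); NaN when no cluster qualifies."""
    sizes = snap.sizes
    q = sizes[sizes >= min_size]
    return float(q.mean()) if q.size else float("nan")


def fraction_trans(state: SystemState) -> float:
    """Fraction of all monomers whose trans slot is occupied."""
    n = state.n_monomers
    if n == 0:
        raise ValueError("state has no monomers")
    return float(np.count_nonzero(state.trans >= 0) / n)


def fraction_cis(state: SystemState) -> float:
    """Fraction of all monomers with at least one occupied cis slot."""
    n = state.n_monomers
    if n == 0:
        raise ValueError("state has no monomers")
    involved = (state.cis_donor >= 0) | (state.cis_acceptor >= 0)
    return float(np.count_nonzero(involved) / n)


def estimate_kd_cis(snapshots: Sequence[SystemState]) -> float:
    """Two-dimensional cis dissociation constant (per um^2).

    Mass-action form: mean over snapshots and planes of
    ``rho_freeDonor * rho_freeAcceptor / rho_cisBond`` with surface densities
    taken per plane.  NaN if no snapshot/plane carries a cis bond.
    """
    terms = []
    for st in snapshots:
        area = st.domain.area_um2
        for plane in (0, 1):
            sel = st.plane == plane
            if not sel.any():
                continue
            n_bond = int(np.count_nonzero(sel & (st.cis_donor >= 0)))
            if n_bond == 0:
                continue
            n_fd = int(np.count_nonzero(sel & (st.cis_donor < 0)))
            n_fa = int(np.count_nonzero(sel & (st.cis_acceptor < 0)))
            terms.append((n_fd / area) * (n_fa / area) / (n_bond / area))
    return float(np.mean(terms)) if terms else float("nan")


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


def msd(
    traj: np.ndarray,
    times: np.ndarray,
    lags: Optional[Sequence[int]] = None,
    mode: str = "both",
) -> MsdCurve:
    """Mean squared displacement of unwrapped trajectories.

    ``traj`` has shape (S, N, 2) with uniform sampling.  ``mode="both"``
    (default) averages over all time origins and all particles (TA+EA MSD);
    ``mode="ensemble"`` uses only the t=0 origin.  ``lags`` are in sample
    units; lags beyond the trajectory length are reported as NaN with zero
    contributing pairs.
    """
    S = traj.shape[0]
    if S < 2:
        raise ValueError("need at least two samples for an MSD")
    dt_s = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt_s, rtol=1e-6, atol=1e-12):
        raise ValueError("trajectory samples must be uniformly spaced")
    if lags is None:
        lags = _default_lags(S)
    vals = np.full(len(lags), np.nan)
    nc = np.zeros(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        if lag <= 0 or lag >= S:
            continue
        if mode == "both":
            d = traj[lag:] - traj[:-lag]
        elif mode == "ensemble":
            d = traj[lag : lag + 1] - traj[0:1]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        sq = np.einsum("...k,...k->...", d, d)
        vals[k] = float(sq.mean())
        nc[k] = sq.size
    return MsdCurve(lags=np.asarray(lags, dtype=float) * dt_s, msd=vals, n_contributing=nc)


def _default_lags(S: int, n: int = 60) -> np.ndarray:
    raw = np.unique(np.round(np.logspace(0, math.log10(S - 1), n)).astype(int))
    return raw[(raw >= 1) & (raw < S)]


def msd_loglog_slope(curve: MsdCurve, lag_window: tuple) -> float:
    """Least-squares slope of log MSD vs log lag over ``lag_window`` (s)."""
    lo, hi = lag_window
    sel = (curve.lags >= lo) & (curve.lags <= hi) & np.isfinite(curve.msd) & (curve.msd > 0)
    if np.count_nonzero(sel) < 2:
        return float("nan")
    return float(np.polyfit(np.log(curve.lags[sel]), np.log(curve.msd[sel]), 1)[0])


# ---------------------------------------------------------------------------
# lifetime tracking
# ---------------------------------------------------------------------------


def track_lifetimes(
    snapshots: Sequence[ClusterSnapshot], min_size: int = 2
) -> List[ClusterTrack]:
    """Match clusters across uniformly spaced snapshots by maximal member
    overlap.

    A track is born when a component first reaches ``min_size``; it continues
    to the successor cluster (size >= ``min_size``) sharing the largest
    member count, provided the overlap covers at least half of the smaller
    set, and dies when no successor qualifies.  A successor continues at most
    one track (largest overlap wins; ties break on the lowest minimum member
    id).  Tracks alive at the last snapshot are right-censored.
    """
    times = np.array([s.time for s in snapshots])
    if len(times) >= 3 and not np.allclose(np.diff(times), times[1] - times[0],
                                           rtol=1e-6, atol=1e-12):
        raise ValueError("snapshots must be uniformly spaced in time")

    tracks: List[ClusterTrack] = []
    # active: list of (track index, member set)
    active: List[tuple] = []
    for snap in snapshots:
        comps = [set(map(int, c)) for c in snap.clusters if len(c) >= min_size]
        claimed = [False] * len(comps)
        survivors: List[tuple] = []
        # all qualifying (track, successor) matches, resolved greedily by
        # overlap desc, then lowest minimum member id, then track id
        candidates = []
        for ai, (ti, members) in enumerate(active):
            for ci, comp in enumerate(comps):
                ov = len(members & comp)
                if ov == 0 or ov * 2 < min(len(members), len(comp)):
                    continue
                candidates.append((-ov, min(comp), ti, ai, ci))
        candidates.sort()
        matched_tracks = set()
        for _ov, _mm, ti, ai, ci in candidates:
            if ti in matched_tracks or claimed[ci]:
                continue
            matched_tracks.add(ti)
            claimed[ci] = True
            tracks[ti].sizes.append(len(comps[ci]))
            survivors.append((ti, comps[ci]))
        for ti, _members in active:
            if ti not in matched_tracks:
                tracks[ti].death = snap.time
        for ci, comp in enumerate(comps):
            if not claimed[ci]:
                t = ClusterTrack(track_id=len(tracks), birth=snap.time, death=None,
                                 sizes=[len(comp)])
                tracks.append(t)
                survivors.append((t.track_id, comp))
        active = survivors
    for ti, _ in active:
        tracks[ti].censored = True
    return tracks


def mean_lifetime(tracks: Sequence[ClusterTrack]) -> float:
    """Mean lifetime over completed (non-censored) tracks; NaN if none."""
    lt = [t.lifetime for t in tracks if not t.censored and t.lifetime is not None]
    return float(np.mean(lt)) if lt else float("nan")


# ---------------------------------------------------------------------------
# spatial patterning
# ---------------------------------------------------------------------------


def _qualifying_centroids(snap: ClusterSnapshot, min_size: int) -> np.ndarray:
    sel = snap.sizes >= min_size
    return snap.centroids[sel]


def nnd(snap: ClusterSnapshot, dom: PeriodicDomain, min_size: int = 5) -> float:
    """Mean nearest-neighbour distance (nm) between centroids of qualifying
    clusters; NaN with fewer than two qualifying clusters."""
    cents = _qualifying_centroids(snap, min_size)
    k = len(cents)
    if k < 2:
        return float("nan")
    dx = cents[:, None, 0] - cents[None, :, 0]
    dy = cents[:, None, 1] - cents[None, :, 1]
    dx -= dom.width * np.floor(dx / dom.width + 0.5)
    dy -= dom.height * np.floor(dy / dom.height + 0.5)
    d = np.hypot(dx, dy)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def size_cv(snap: ClusterSnapshot, min_size: int = 5) -> float:
    """Population coefficient of variation of qualifying cluster sizes; NaN
    with fewer than two qualifying clusters."""
    sizes = snap.sizes
    q = sizes[sizes >= min_size]
    if q.size < 2:
        return float("nan")
    return float(q.std(ddof=0) / q.mean())


# ---------------------------------------------------------------------------
# run-level summary
# ---------------------------------------------------------------------------


def summarize_run(result, min_size: int = 5, kd_fraction: float = 0.5) -> dict:
    """Standard summary panel over a :class:`~cadclust.engine.RunResult`.

    KD uses the late ``kd_fraction`` of snapshots; MSD exponents are fitted
    over the shortest and longest decades of available lags.
    """
    final = result.final_state
    snap = find_clusters(final)
    out = {
        "max_cluster_size": max_cluster_size(snap),
        "mean_cluster_size": mean_cluster_size(snap, min_size=min_size),
        "fraction_trans": fraction_trans(final),
        "fraction_cis": fraction_cis(final),
        "nnd": nnd(snap, result.domain, min_size=min_size),
        "size_cv": size_cv(snap, min_size=min_size),
    }
    n_snap = len(result.snapshots)
    late = result.snapshots[int(math.ceil(n_snap * (1 - kd_fraction))):] if n_snap else []
    out["kd_cis"] = estimate_kd_cis(late) if late else float("nan")
    if result.traj.shape[0] >= 3:
        curve = msd(result.traj, result.traj_times)
        lag_min = curve.lags[0]
        lag_max = curve.lags[-1]
        out["msd_alpha_short"] = msd_loglog_slope(curve, (lag_min, 10 * lag_min))
        out["msd_alpha_long"] = msd_loglog_slope(curve, (lag_max / 10, lag_max))
    else:
        out["msd_alpha_short"] = float("nan")
        out["msd_alpha_long"] = float("nan")
    if n_snap >= 3:
        snaps = [find_clusters(s) for s in result.snapshots]
        out["mean_lifetime"] = mean_lifetime(track_lifetimes(snaps))
    else:
        out["mean_lifetime"] = float("nan")
    return out
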