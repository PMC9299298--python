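"""Numba kernels for the per-step update loop.

The state lives in flat numpy arrays (see :class:`cadclust.state.SystemState`)
and one kernel call advances a whole chunk of steps: turnover -> diffusion
with obstruction rejection -> rotation -> dissociation -> association with
geometry adjustment, advancing the clock by ``dt`` per step.

Spatial acceleration.  Filaments are cut into short collinear *chunks*
(shorter than one grid cell) and binned into two coarse grids: an
obstruction grid over whole filaments, padded by more than one step length,
and a binding grid over the binding sub-segments, padded by more than the
cadherin-actin cutoff.  A single cell lookup at a monomer's position then
sees every chunk its move path or binding test could touch.  Monomers are
binned each step (after moving) into a cell list whose cell size exceeds the
largest eligibility distance, so no eligible pair is missed.

Performance notes: move directions are drawn from a 4096-entry unit-vector
table (0.09 degree resolution, immaterial next to the rotational step);
per-monomer cos/sin of the orientation are cached and updated by rotation
identities, with a periodic exact refresh to cancel float drift.

Randomness comes from an in-kernel xorshift128+ stream, seeded once per
kernel call; callers derive per-chunk seeds from the run seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .geometry import _mi1, _point_seg_dist, _segments_cross, _wrap1
from .kinetics import _circ

NONE = -1
TWO_PI = 2.0 * math.pi
N_DIR = 4096  # move-direction table resolution
REFRESH_EVERY = 4096  # steps between exact cos/sin refreshes
OB_CELL = 25.0  # nm, obstruction grid cell (and max obstruction chunk length)
BI_CELL = 20.0  # nm, binding grid cell (and max binding chunk length)

# counts[] layout
C_TRANS_MADE = 0
C_TRANS_BROKEN = 1
C_CIS_MADE = 2
C_CIS_BROKEN = 3
C_ACTIN_MADE = 4
C_ACTIN_BROKEN = 5
C_TRANS_PAIR_STEPS = 6
C_MOVES_ACCEPTED = 7
C_MOVES_REJECTED = 8
C_TURNOVER_REMOVALS = 9
C_PROPOSALS = 10
N_COUNTS = 11


# ---------------------------------------------------------------------------
# in-kernel PRNG: xorshift128+ seeded via splitmix64.  Inlined draws cost a
# few ns each (the dominant per-step cost otherwise); the stream is fully
# determined by the chunk seed.
# ---------------------------------------------------------------------------

U64 = np.uint64
INV_2_53 = 1.1102230246251565e-16  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + U64(0x9E3779B97F4A7C15)) & U64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True)
def _rng_seed(st, seed):
    z = U64(seed)
    z = _splitmix64(z)
    st[0] = z
    z = _splitmix64(z)
    st[1] = z
    if st[0] == U64(0) and st[1] == U64(0):
        st[0] = U64(0x9E3779B97F4A7C15)


@njit(cache=True, inline="always")
def _rng_next(st):
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 = s1 ^ (s1 << U64(23))
    s1 = s1 ^ s0 ^ (s1 >> U64(18)) ^ (s0 >> U64(5))
    st[1] = s1
    return (s1 + s0) & U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rng_unif(st):
    """Uniform double in [0, 1)."""
    return float(_rng_next(st) >> U64(11)) * INV_2_53


@njit(cache=True, inline="always")
def _rng_below(st, n):
    """Uniform integer in [0, n)."""
    k = int(_rng_unif(st) * n)
    if k >= n:
        k = n - 1
    return k


@njit(cache=True)
def _wrap_fast(x, L):
    # |displacement| < L by construction
    if x >= L:
        return x - L
    if x < 0.0:
        return x + L
    return x


@njit(cache=True)
def _fill_chunks(fil_ax, fil_ay, fil_th, fil_len, fil_b0, fil_b1,
                 ob_start, och_ax, och_ay, och_dx, och_dy, och_fil,
                 bi_start, bch_ax, bch_ay, bch_dx, bch_dy, bch_fil, f):
    """(Re)compute the obstruction and binding chunks of filament ``f``."""
    ux = math.cos(fil_th[f])
    uy = math.sin(fil_th[f])
    L = fil_len[f]
    k = ob_start[f + 1] - ob_start[f]
    stepl = L / k
    for jj in range(k):
        p = ob_start[f] + jj
        och_fil[p] = f
        och_ax[p] = fil_ax[f] + jj * stepl * ux
        och_ay[p] = fil_ay[f] + jj * stepl * uy
        och_dx[p] = stepl * ux
        och_dy[p] = stepl * uy
    kb = bi_start[f + 1] - bi_start[f]
    if kb > 0:
        s0 = fil_b0[f] * L
        blen = (fil_b1[f] - fil_b0[f]) * L
        stepb = blen / kb
        for jj in range(kb):
            p = bi_start[f] + jj
            bch_fil[p] = f
            bch_ax[p] = fil_ax[f] + (s0 + jj * stepb) * ux
            bch_ay[p] = fil_ay[f] + (s0 + jj * stepb) * uy
            bch_dx[p] = stepb * ux
            bch_dy[p] = stepb * uy


@njit(cache=True)
def _build_grid(ch_ax, ch_ay, ch_dx, ch_dy, W, H, ncx, ncy, pad):
    """CSR cell list of chunks; bounding boxes padded by ``pad`` so a single
    cell query at a point covers every chunk within ``pad`` of it."""
    P = ch_ax.shape[0]
    ncell = ncx * ncy
    cw = W / ncx
    ch_ = H / ncy
    count = np.zeros(ncell + 1, np.int64)
    for p in range(P):
        xa = ch_ax[p]
        xb = ch_ax[p] + ch_dx[p]
        ya = ch_ay[p]
        yb = ch_ay[p] + ch_dy[p]
        cx0 = int(math.floor((min(xa, xb) - pad) / cw))
        cx1 = int(math.floor((max(xa, xb) + pad) / cw))
        cy0 = int(math.floor((min(ya, yb) - pad) / ch_))
        cy1 = int(math.floor((max(ya, yb) + pad) / ch_))
        if cx1 - cx0 >= ncx:
            cx1 = cx0 + ncx - 1
        if cy1 - cy0 >= ncy:
            cy1 = cy0 + ncy - 1
        for cy in range(cy0, cy1 + 1):
            for cx in range(cx0, cx1 + 1):
                c = (cy % ncy) * ncx + (cx % ncx)
                count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    items = np.empty(count[ncell], np.int64)
    cursor = count[:-1].copy()
    for p in range(P):
        xa = ch_ax[p]
        xb = ch_ax[p] + ch_dx[p]
        ya = ch_ay[p]
        yb = ch_ay[p] + ch_dy[p]
        cx0 = int(math.floor((min(xa, xb) - pad) / cw))
        cx1 = int(math.floor((max(xa, xb) + pad) / cw))
        cy0 = int(math.floor((min(ya, yb) - pad) / ch_))
        cy1 = int(math.floor((max(ya, yb) + pad) / ch_))
        if cx1 - cx0 >= ncx:
            cx1 = cx0 + ncx - 1
        if cy1 - cy0 >= ncy:
            cy1 = cy0 + ncy - 1
        for cy in range(cy0, cy1 + 1):
            for cx in range(cx0, cx1 + 1):
                c = (cy % ncy) * ncx + (cx % ncx)
                items[cursor[c]] = p
                cursor[c] += 1
    return count, items


@njit(cache=True)
def _cell_of(x, y, W, H, ncx, ncy):
    cx = int(x / (W / ncx))
    if cx >= ncx:
        cx = ncx - 1
    elif cx < 0:
        cx = 0
    cy = int(y / (H / ncy))
    if cy >= ncy:
        cy = ncy - 1
    elif cy < 0:
        cy = 0
    return cy * ncx + cx


@njit(cache=True, inline="always")
def _cell_fast(x, y, invx, invy, ncx, ncy):
    cx = int(x * invx)
    if cx >= ncx:
        cx = ncx - 1
    cy = int(y * invy)
    if cy >= ncy:
        cy = ncy - 1
    return cy * ncx + cx


@njit(cache=True)
def _path_blocked(x, y, ddx, ddy, pl,
                  och_ax, och_ay, och_dx, och_dy, och_pl,
                  optr, oitems, invox, invoy, nox, noy, W, H):
    c = _cell_fast(x, y, invox, invoy, nox, noy)
    for it in range(optr[c], optr[c + 1]):
        p = oitems[it]
        if och_pl[p] != pl:
            continue
        if _segments_cross(x, y, ddx, ddy, och_ax[p], och_ay[p], och_dx[p], och_dy[p], W, H):
            return True
    return False


@njit(cache=True)
def _clean_for_reloc(m, cisd, cisa, abond, trans):
    """True if monomer ``m`` (and its trans partner, which moves with it)
    carries no cis or actin bond besides the one being formed at ``m``'s
    currently free slot."""
    if abond[m] >= 0:
        return False
    p = trans[m]
    if p >= 0:
        if cisd[p] >= 0 or cisa[p] >= 0 or abond[p] >= 0:
            return False
    return True


@njit(cache=True)
def _move_rigid(m, ddx, ddy, pos, unwrapped, trans, W, H):
    pos[m, 0] = _wrap1(pos[m, 0] + ddx, W)
    pos[m, 1] = _wrap1(pos[m, 1] + ddy, H)
    unwrapped[m, 0] += ddx
    unwrapped[m, 1] += ddy
    p = trans[m]
    if p >= 0:
        pos[p, 0] = pos[m, 0]
        pos[p, 1] = pos[m, 1]
        unwrapped[p, 0] += ddx
        unwrapped[p, 1] += ddy


@njit(cache=True)
def _sync_theta(m, src_theta, src_c, src_s, theta, costh, sinth, trans):
    """Set monomer ``m``'s orientation to ``src`` exactly, rotating its trans
    partner by the same increment to preserve the packing offset."""
    dth = _circ(src_theta - theta[m])
    theta[m] = src_theta % TWO_PI
    costh[m] = src_c
    sinth[m] = src_s
    p = trans[m]
    if p >= 0:
        theta[p] = (theta[p] + dth) % TWO_PI
        costh[p] = math.cos(theta[p])
        sinth[p] = math.sin(theta[p])


@njit(cache=True)
def _set_theta_offset(j, i, sign, th_trans, theta, costh, sinth):
    """theta_j := theta_i + sign*th_trans, exact for the 90-degree case."""
    theta[j] = (theta[i] + sign * th_trans) % TWO_PI
    if th_trans == 0.5 * math.pi:
        # quarter-turn: rotate the cached unit vector exactly
        costh[j] = -sign * sinth[i]
        sinth[j] = sign * costh[i]
    else:
        costh[j] = math.cos(theta[j])
        sinth[j] = math.sin(theta[j])


@njit(cache=True, inline="always")
def _mi_half(d, L, halfL):
    # minimal image for |d| < L (differences of wrapped coordinates)
    if d >= halfL:
        return d - L
    if d < -halfL:
        return d + L
    return d


@njit(cache=True)
def simulate_chunk(nsteps, seed,
                   pos, theta, plane, trans, cisd, cisa, abond, unwrapped,
                   fil_ax, fil_ay, fil_th, fil_len, fil_b0, fil_b1, fil_birth, fil_plane,
                   ob_start, bi_start,
                   W, H, dt, step_len, rot_step,
                   dc_trans, dc_cis, dc_ca, r_cad, ac, th_trans,
                   p_ass_t, p_dis_t, p_ass_c, p_dis_c, p_ass_a, p_dis_a,
                   p_turn, obstruct_on, binding_on, raw_angle,
                   time0, traj_every, traj_out, counts):
    rstate = np.empty(2, np.uint64)
    _rng_seed(rstate, seed)
    N = pos.shape[0]
    M = fil_ax.shape[0]
    n_och = ob_start[M] if M > 0 else 0
    n_bch = bi_start[M] if M > 0 else 0

    # --- move-direction table --------------------------------------------
    dirc = np.empty(N_DIR)
    dirs = np.empty(N_DIR)
    for k in range(N_DIR):
        a = TWO_PI * k / N_DIR
        dirc[k] = math.cos(a)
        dirs[k] = math.sin(a)

    # --- cached orientation unit vectors ---------------------------------
    costh = np.empty(N)
    sinth = np.empty(N)
    for i in range(N):
        costh[i] = math.cos(theta[i])
        sinth[i] = math.sin(theta[i])

    # --- actin chunk grids -----------------------------------------------
    och_ax = np.empty(n_och)
    och_ay = np.empty(n_och)
    och_dx = np.empty(n_och)
    och_dy = np.empty(n_och)
    och_fil = np.empty(n_och, np.int64)
    och_pl = np.empty(n_och, np.int64)
    bch_ax = np.empty(n_bch)
    bch_ay = np.empty(n_bch)
    bch_dx = np.empty(n_bch)
    bch_dy = np.empty(n_bch)
    bch_fil = np.empty(n_bch, np.int64)
    bch_pl = np.empty(n_bch, np.int64)
    nox = max(1, int(W // OB_CELL))
    noy = max(1, int(H // OB_CELL))
    nbx = max(1, int(W // BI_CELL))
    nby = max(1, int(H // BI_CELL))
    pad_ob = step_len + 1.0
    pad_bi = dc_ca + 1.0
    optr = np.zeros(2, np.int64)
    oitems = np.empty(0, np.int64)
    bptr = np.zeros(2, np.int64)
    bitems = np.empty(0, np.int64)
    if M > 0:
        for f in range(M):
            _fill_chunks(fil_ax, fil_ay, fil_th, fil_len, fil_b0, fil_b1,
                         ob_start, och_ax, och_ay, och_dx, och_dy, och_fil,
                         bi_start, bch_ax, bch_ay, bch_dx, bch_dy, bch_fil, f)
        for p in range(n_och):
            och_pl[p] = fil_plane[och_fil[p]]
        for p in range(n_bch):
            bch_pl[p] = fil_plane[bch_fil[p]]
        optr, oitems = _build_grid(och_ax, och_ay, och_dx, och_dy, W, H, nox, noy, pad_ob)
        bptr, bitems = _build_grid(bch_ax, bch_ay, bch_dx, bch_dy, W, H, nbx, nby, pad_bi)

    # --- monomer cell list (sized to the largest eligibility distance;
    #     built after the move phase, so no extra step margin is needed) ---
    cm = dc_cis + 2.0 * r_cad + 0.2
    nmx = int(W / cm)
    nmy = int(H / cm)
    use_grid = nmx >= 3 and nmy >= 3 and N >= 2
    if not use_grid:
        nmx = 1
        nmy = 1
    mptr = np.zeros(nmx * nmy + 1, np.int64)
    mitems = np.empty(N, np.int64)
    mcell = np.empty(N, np.int64)
    cursor = np.empty(nmx * nmy, np.int64)
    # monomers with every pairwise slot occupied can join no new pair bond;
    # marking them once per step lets dense lattice interiors be skipped fast
    gated = np.empty(N, np.int8)

    perm = np.empty(N, np.int64)
    # per-site "one attempt per step" stamps
    st_t = np.full(N, -1, np.int64)
    st_cd = np.full(N, -1, np.int64)
    st_ca = np.full(N, -1, np.int64)
    st_ab = np.full(N, -1, np.int64)
    fil_seen = np.full(M if M > 0 else 1, -1, np.int64)

    cap = 24 * N + 64
    pk = np.empty(cap, np.int8)
    pa = np.empty(cap, np.int64)
    pb = np.empty(cap, np.int64)
    order = np.empty(cap, np.int64)

    rmax = dc_cis + 2.0 * r_cad
    rmax2 = rmax * rmax
    dct2 = dc_trans * dc_trans
    dcc2 = dc_cis * dc_cis
    sep = 2.0 * r_cad
    halfW = 0.5 * W
    halfH = 0.5 * H
    cos_ac = math.cos(ac)
    invmx = nmx / W
    invmy = nmy / H
    invox = nox / W
    invoy = noy / H
    invbx = nbx / W
    invby = nby / H

    for s in range(nsteps):
        tnow = time0 + (s + 1) * dt

        if s % REFRESH_EVERY == REFRESH_EVERY - 1:
            for i in range(N):
                costh[i] = math.cos(theta[i])
                sinth[i] = math.sin(theta[i])

        # (1) actin turnover --------------------------------------------
        if p_turn > 0.0 and M > 0:
            dirty = False
            for f in range(M):
                if _rng_unif(rstate) >= p_turn:
                    continue
                dirty = True
                counts[C_TURNOVER_REMOVALS] += 1
                for i in range(N):
                    if abond[i] == f:
                        abond[i] = NONE
                        counts[C_ACTIN_BROKEN] += 1
                fil_ax[f] = _rng_unif(rstate) * W
                fil_ay[f] = _rng_unif(rstate) * H
                fil_th[f] = _rng_unif(rstate) * TWO_PI
                bf = fil_b1[f] - fil_b0[f]
                if bf < 1.0:
                    b0 = _rng_unif(rstate) * (1.0 - bf)
                else:
                    b0 = 0.0
                fil_b0[f] = b0
                fil_b1[f] = b0 + bf
                fil_birth[f] = tnow
                _fill_chunks(fil_ax, fil_ay, fil_th, fil_len, fil_b0, fil_b1,
                             ob_start, och_ax, och_ay, och_dx, och_dy, och_fil,
                             bi_start, bch_ax, bch_ay, bch_dx, bch_dy, bch_fil, f)
            if dirty:
                optr, oitems = _build_grid(och_ax, och_ay, och_dx, och_dy,
                                           W, H, nox, noy, pad_ob)
                bptr, bitems = _build_grid(bch_ax, bch_ay, bch_dx, bch_dy,
                                           W, H, nbx, nby, pad_bi)

        # (2) diffusion of mobile units, shuffled order ------------------
        if step_len > 0.0:
            for i in range(N):
                perm[i] = i
            for i in range(N - 1, 0, -1):
                j = _rng_below(rstate, i + 1)
                tmp = perm[i]
                perm[i] = perm[j]
                perm[j] = tmp
            for idx in range(N):
                i = perm[idx]
                if cisd[i] >= 0 or cisa[i] >= 0 or abond[i] >= 0:
                    continue
                j = trans[i]
                if j >= 0:
                    if j < i:
                        continue  # dimer handled from its lower id
                    if cisd[j] >= 0 or cisa[j] >= 0 or abond[j] >= 0:
                        continue
                k = _rng_below(rstate, N_DIR)
                ddx = step_len * dirc[k]
                ddy = step_len * dirs[k]
                blocked = False
                if obstruct_on and n_och > 0:
                    blocked = _path_blocked(
                        pos[i, 0], pos[i, 1], ddx, ddy, plane[i],
                        och_ax, och_ay, och_dx, och_dy, och_pl,
                        optr, oitems, invox, invoy, nox, noy, W, H)
                    if not blocked and j >= 0:
                        blocked = _path_blocked(
                            pos[i, 0], pos[i, 1], ddx, ddy, plane[j],
                            och_ax, och_ay, och_dx, och_dy, och_pl,
                            optr, oitems, invox, invoy, nox, noy, W, H)
                if blocked:
                    counts[C_MOVES_REJECTED] += 1
                else:
                    counts[C_MOVES_ACCEPTED] += 1
                    pos[i, 0] = _wrap_fast(pos[i, 0] + ddx, W)
                    pos[i, 1] = _wrap_fast(pos[i, 1] + ddy, H)
                    unwrapped[i, 0] += ddx
                    unwrapped[i, 1] += ddy
                    if j >= 0:
                        pos[j, 0] = pos[i, 0]
                        pos[j, 1] = pos[i, 1]
                        unwrapped[j, 0] += ddx
                        unwrapped[j, 1] += ddy

        # (3) rotation ---------------------------------------------------
        if rot_step > 0.0:
            cr = math.cos(rot_step)
            sr = math.sin(rot_step)
            for i in range(N):
                if cisd[i] >= 0 or cisa[i] >= 0:
                    continue
                j = trans[i]
                if j >= 0:
                    if j < i:
                        continue
                    if cisd[j] >= 0 or cisa[j] >= 0:
                        continue
                if _rng_unif(rstate) < 0.5:
                    dth = rot_step
                    sgn = sr
                else:
                    dth = -rot_step
                    sgn = -sr
                theta[i] = (theta[i] + dth) % TWO_PI
                c0 = costh[i]
                costh[i] = c0 * cr - sinth[i] * sgn
                sinth[i] = sinth[i] * cr + c0 * sgn
                if j >= 0:
                    theta[j] = (theta[j] + dth) % TWO_PI
                    c0 = costh[j]
                    costh[j] = c0 * cr - sinth[j] * sgn
                    sinth[j] = sinth[j] * cr + c0 * sgn

        # (4) dissociation ------------------------------------------------
        for i in range(N):
            j = trans[i]
            if j > i:
                counts[C_TRANS_PAIR_STEPS] += 1
                if p_dis_t > 0.0 and _rng_unif(rstate) < p_dis_t:
                    trans[i] = NONE
                    trans[j] = NONE
                    counts[C_TRANS_BROKEN] += 1
            j = cisd[i]
            if j >= 0 and p_dis_c > 0.0:
                if _rng_unif(rstate) < p_dis_c:
                    cisd[i] = NONE
                    cisa[j] = NONE
                    counts[C_CIS_BROKEN] += 1
            if abond[i] >= 0 and p_dis_a > 0.0:
                if _rng_unif(rstate) < p_dis_a:
                    abond[i] = NONE
                    counts[C_ACTIN_BROKEN] += 1

        # (5) association --------------------------------------------------
        nprop = 0
        for i in range(N):
            if trans[i] >= 0 and cisd[i] >= 0 and cisa[i] >= 0:
                gated[i] = 1
            else:
                gated[i] = 0
        if use_grid:
            ncellm = nmx * nmy
            for c in range(ncellm + 1):
                mptr[c] = 0
            for i in range(N):
                c = _cell_fast(pos[i, 0], pos[i, 1], invmx, invmy, nmx, nmy)
                mcell[i] = c
                mptr[c + 1] += 1
            for c in range(ncellm):
                mptr[c + 1] += mptr[c]
            for c in range(ncellm):
                cursor[c] = mptr[c]
            for i in range(N):
                c = mcell[i]
                mitems[cursor[c]] = i
                cursor[c] += 1

        for i in range(N):
            # pair proposals; skip monomers with no free pairwise slot
            if gated[i] == 0:
                xi = pos[i, 0]
                yi = pos[i, 1]
                if use_grid:
                    ci = mcell[i]
                    cyi = ci // nmx
                    cxi = ci - cyi * nmx
                    for oy in range(-1, 2):
                        cy = cyi + oy
                        if cy < 0:
                            cy += nmy
                        elif cy >= nmy:
                            cy -= nmy
                        cyb = cy * nmx
                        for ox in range(-1, 2):
                            cx = cxi + ox
                            if cx < 0:
                                cx += nmx
                            elif cx >= nmx:
                                cx -= nmx
                            c = cyb + cx
                            for it in range(mptr[c], mptr[c + 1]):
                                j = mitems[it]
                                if j <= i or gated[j] == 1:
                                    continue
                                # fast in-range rejection, then slot/angle
                                # eligibility (trans across planes, cis both
                                # donor->acceptor orderings on one plane)
                                dx = _mi_half(pos[j, 0] - xi, W, halfW)
                                if dx > rmax or dx < -rmax:
                                    continue
                                dy = _mi_half(pos[j, 1] - yi, H, halfH)
                                d2 = dx * dx + dy * dy
                                if d2 > rmax2:
                                    continue
                                if plane[i] != plane[j]:
                                    if trans[i] < 0 and trans[j] < 0 and d2 < dct2:
                                        # dev from +/-90 packing < ac  <=>  |sin dtheta| > cos ac
                                        sd = sinth[j] * costh[i] - costh[j] * sinth[i]
                                        cd = costh[i] * costh[j] + sinth[i] * sinth[j]
                                        ok = (cd > cos_ac) if raw_angle else (abs(sd) > cos_ac)
                                        if ok and nprop < cap:
                                            pk[nprop] = 0
                                            pa[nprop] = i
                                            pb[nprop] = j
                                            nprop += 1
                                else:
                                    fwd = cisd[i] < 0 and cisa[j] < 0
                                    rev = cisd[j] < 0 and cisa[i] < 0
                                    # parallel packing: dev < ac  <=>  cos dtheta > cos ac
                                    if (fwd or rev) and (costh[i] * costh[j]
                                                         + sinth[i] * sinth[j]) > cos_ac:
                                        ox2 = r_cad * (costh[i] + costh[j])
                                        oy2 = r_cad * (sinth[i] + sinth[j])
                                        if fwd:
                                            vx = dx - ox2
                                            vy = dy - oy2
                                            if vx * vx + vy * vy < dcc2 and nprop < cap:
                                                pk[nprop] = 1
                                                pa[nprop] = i
                                                pb[nprop] = j
                                                nprop += 1
                                        if rev:
                                            vx = -dx - ox2
                                            vy = -dy - oy2
                                            if vx * vx + vy * vy < dcc2 and nprop < cap:
                                                pk[nprop] = 1
                                                pa[nprop] = j
                                                pb[nprop] = i
                                                nprop += 1
                elif N >= 2:
                    for j in range(i + 1, N):
                        if gated[j] == 1:
                            continue
                        dx = _mi_half(pos[j, 0] - xi, W, halfW)
                        dy = _mi_half(pos[j, 1] - yi, H, halfH)
                        d2 = dx * dx + dy * dy
                        if d2 > rmax2:
                            continue
                        if plane[i] != plane[j]:
                            if trans[i] < 0 and trans[j] < 0 and d2 < dct2:
                                sd = sinth[j] * costh[i] - costh[j] * sinth[i]
                                cd = costh[i] * costh[j] + sinth[i] * sinth[j]
                                ok = (cd > cos_ac) if raw_angle else (abs(sd) > cos_ac)
                                if ok and nprop < cap:
                                    pk[nprop] = 0
                                    pa[nprop] = i
                                    pb[nprop] = j
                                    nprop += 1
                        else:
                            fwd = cisd[i] < 0 and cisa[j] < 0
                            rev = cisd[j] < 0 and cisa[i] < 0
                            if (fwd or rev) and (costh[i] * costh[j]
                                                 + sinth[i] * sinth[j]) > cos_ac:
                                ox2 = r_cad * (costh[i] + costh[j])
                                oy2 = r_cad * (sinth[i] + sinth[j])
                                if fwd:
                                    vx = dx - ox2
                                    vy = dy - oy2
                                    if vx * vx + vy * vy < dcc2 and nprop < cap:
                                        pk[nprop] = 1
                                        pa[nprop] = i
                                        pb[nprop] = j
                                        nprop += 1
                                if rev:
                                    vx = -dx - ox2
                                    vy = -dy - oy2
                                    if vx * vx + vy * vy < dcc2 and nprop < cap:
                                        pk[nprop] = 1
                                        pa[nprop] = j
                                        pb[nprop] = i
                                        nprop += 1

            # cadherin-actin proposals
            if binding_on and n_bch > 0 and abond[i] < 0 and p_ass_a > 0.0:
                tag = s * N + i
                c = _cell_fast(pos[i, 0], pos[i, 1], invbx, invby, nbx, nby)
                for it in range(bptr[c], bptr[c + 1]):
                    p = bitems[it]
                    if bch_pl[p] != plane[i]:
                        continue
                    f = bch_fil[p]
                    if fil_seen[f] == tag:
                        continue
                    d = _point_seg_dist(pos[i, 0], pos[i, 1],
                                        bch_ax[p], bch_ay[p], bch_dx[p], bch_dy[p],
                                        W, H)
                    if d < dc_ca:
                        fil_seen[f] = tag
                        if nprop < cap:
                            pk[nprop] = 2
                            pa[nprop] = i
                            pb[nprop] = f
                            nprop += 1

        counts[C_PROPOSALS] += nprop
        # shuffle and process proposals
        if nprop > 0:
            for t in range(nprop):
                order[t] = t
            for t in range(nprop - 1, 0, -1):
                u = _rng_below(rstate, t + 1)
                tmp = order[t]
                order[t] = order[u]
                order[u] = tmp
            for t in range(nprop):
                q = order[t]
                kind = pk[q]
                i = pa[q]
                j = pb[q]
                if kind == 0:
                    if st_t[i] == s or st_t[j] == s or trans[i] >= 0 or trans[j] >= 0:
                        continue
                    st_t[i] = s
                    st_t[j] = s
                    if _rng_unif(rstate) < p_ass_t:
                        trans[i] = j
                        trans[j] = i
                        counts[C_TRANS_MADE] += 1
                        # mobility-aware coaxial alignment
                        ri = cisd[i] < 0 and cisa[i] < 0 and abond[i] < 0
                        rj = cisd[j] < 0 and cisa[j] < 0 and abond[j] < 0
                        dx = _mi1(pos[j, 0] - pos[i, 0], W)
                        dy = _mi1(pos[j, 1] - pos[i, 1], H)
                        delta = _circ(theta[j] - theta[i])
                        if abs(_circ(delta - th_trans)) <= abs(_circ(delta + th_trans)):
                            sign = 1.0
                        else:
                            sign = -1.0
                        if ri and rj:
                            pos[i, 0] = _wrap1(pos[i, 0] + 0.5 * dx, W)
                            pos[i, 1] = _wrap1(pos[i, 1] + 0.5 * dy, H)
                            unwrapped[i, 0] += 0.5 * dx
                            unwrapped[i, 1] += 0.5 * dy
                            pos[j, 0] = pos[i, 0]
                            pos[j, 1] = pos[i, 1]
                            unwrapped[j, 0] -= 0.5 * dx
                            unwrapped[j, 1] -= 0.5 * dy
                            _set_theta_offset(j, i, sign, th_trans, theta, costh, sinth)
                        elif rj:
                            pos[j, 0] = pos[i, 0]
                            pos[j, 1] = pos[i, 1]
                            unwrapped[j, 0] -= dx
                            unwrapped[j, 1] -= dy
                            _set_theta_offset(j, i, sign, th_trans, theta, costh, sinth)
                        elif ri:
                            pos[i, 0] = pos[j, 0]
                            pos[i, 1] = pos[j, 1]
                            unwrapped[i, 0] += dx
                            unwrapped[i, 1] += dy
                            _set_theta_offset(i, j, -sign, th_trans, theta, costh, sinth)
                elif kind == 1:
                    # i's donor -> j's acceptor
                    if st_cd[i] == s or st_ca[j] == s or cisd[i] >= 0 or cisa[j] >= 0:
                        continue
                    st_cd[i] = s
                    st_ca[j] = s
                    if _rng_unif(rstate) < p_ass_c:
                        ri = cisa[i] < 0 and _clean_for_reloc(i, cisd, cisa, abond, trans)
                        rj = cisd[j] < 0 and _clean_for_reloc(j, cisd, cisa, abond, trans)
                        cisd[i] = j
                        cisa[j] = i
                        counts[C_CIS_MADE] += 1
                        mover = 0  # 0 none, 1 move i, 2 move j
                        if ri and rj:
                            bi = 1 if trans[i] >= 0 else 0
                            bj = 1 if trans[j] >= 0 else 0
                            mover = 1 if bi < bj else 2
                        elif ri:
                            mover = 1
                        elif rj:
                            mover = 2
                        if mover == 2:
                            ddx = _mi1(pos[i, 0] - pos[j, 0], W) + sep * costh[i]
                            ddy = _mi1(pos[i, 1] - pos[j, 1], H) + sep * sinth[i]
                            _move_rigid(j, ddx, ddy, pos, unwrapped, trans, W, H)
                            _sync_theta(j, theta[i], costh[i], sinth[i],
                                        theta, costh, sinth, trans)
                        elif mover == 1:
                            ddx = _mi1(pos[j, 0] - pos[i, 0], W) - sep * costh[j]
                            ddy = _mi1(pos[j, 1] - pos[i, 1], H) - sep * sinth[j]
                            _move_rigid(i, ddx, ddy, pos, unwrapped, trans, W, H)
                            _sync_theta(i, theta[j], costh[j], sinth[j],
                                        theta, costh, sinth, trans)
                else:
                    if st_ab[i] == s or abond[i] >= 0:
                        continue
                    st_ab[i] = s
                    if _rng_unif(rstate) < p_ass_a:
                        abond[i] = j
                        counts[C_ACTIN_MADE] += 1

        # (6) trajectory recording ----------------------------------------
        if traj_every > 0 and (s + 1) % traj_every == 0:
            r = (s + 1) // traj_every - 1
            for i in range(N):
                traj_out[r, i, 0] = unwrapped[i, 0]
                traj_out[r, i, 1] = unwrapped[i, 1]

    return time0 + nsteps * dt
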