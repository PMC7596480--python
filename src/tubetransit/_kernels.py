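"""Numba kernels: domain membership, specular wall tracing, ensemble stepping.

All kernel coordinates are in metres.  The domain is either a single
cylinder (``STRAIGHT``) or two coaxial cylindrical tubes joined by a cubic
cavity (``TWO_TUBE``).  The axial landmarks are

    0 -- x_in -- x_out -- x_absorb

with the source end plane x = 0 reflecting and the plane x = x_absorb
absorbing over the full contralateral cross-section.
"""

import numpy as np
from numba import njit

STRAIGHT = 0
TWO_TUBE = 1

# region codes
IPSI = 0
CAVITY = 1
CONTRA = 2
OUTSIDE = 3

# absolute slack: 1e-12 m on coordinates, 1e-16 m^2 on squared radii
_EPS = 1e-12
_EPS2 = 1e-16

MAX_REFLECTIONS = 8
_MAX_EVENTS = 32


@njit(cache=True, fastmath=True)
def contains_pt(mode, R, xin, xout, xab, half, x, y, z):
    if x < -_EPS or x > xab + _EPS:
        return False
    r2 = y * y + z * z
    R2 = R * R
    if mode == STRAIGHT:
        return r2 <= R2 + _EPS2
    if x <= xin + _EPS and r2 <= R2 + _EPS2:
        return True
    if x >= xout - _EPS and r2 <= R2 + _EPS2:
        return True
    if xin - _EPS <= x <= xout + _EPS:
        if abs(y) <= half + _EPS and abs(z) <= half + _EPS:
            return True
    return False


@njit(cache=True, fastmath=True)
def region_pt(mode, R, xin, xout, xab, half, x, y, z):
    """Region label; axial boundary planes belong to the downstream region."""
    if not contains_pt(mode, R, xin, xout, xab, half, x, y, z):
        return OUTSIDE
    if x < xin - _EPS:
        return IPSI
    if x < xout - _EPS:
        return CAVITY
    if mode == STRAIGHT:
        return CONTRA
    # on or beyond the contralateral junction plane
    if y * y + z * z <= R * R + _EPS2:
        return CONTRA
    return CAVITY


@njit(cache=True, fastmath=True)
def advance(mode, R, xin, xout, xab, half, x, y, z, ux, uy, uz):
    """Trace one displacement segment through the domain.

    Applies specular reflection at walls (radial normals on cylinder
    sides, axial normals on end/cavity planes), passes freely through the
    tube-mouth disks, and stops on the absorbing plane.  After
    ``MAX_REFLECTIONS`` mirror events the move is rejected and the start
    point is returned with the fallback flag set.

    Returns ``(x, y, z, absorbed, n_reflections, fallback)``.
    """
    x0 = x
    y0 = y
    z0 = z
    R2 = R * R
    nrefl = 0
    for _ in range(_MAX_EVENTS):
        if ux == 0.0 and uy == 0.0 and uz == 0.0:
            return x, y, z, False, nrefl, False

        # classify the current region, direction-aware on junction planes
        if mode == STRAIGHT:
            reg = IPSI  # whole domain behaves like one tube
        else:
            if x < xin - _EPS:
                reg = IPSI
            elif x > xout + _EPS:
                reg = CONTRA
            elif xin + _EPS < x < xout - _EPS:
                reg = CAVITY
            elif x <= xin + _EPS:
                if y * y + z * z <= R2 + _EPS2:
                    reg = IPSI if ux < 0.0 else CAVITY
                else:
                    reg = CAVITY
            else:
                if y * y + z * z <= R2 + _EPS2:
                    reg = CONTRA if ux > 0.0 else CAVITY
                else:
                    reg = CAVITY

        # find the earliest event along t in [0, 1]
        t_hit = 2.0
        kind = -1  # 0 cylinder wall, 1 axial-plane wall, 2 junction pass,
        #            3 y-face wall, 4 z-face wall, 6 absorbing plane
        plane_x = 0.0

        if mode == STRAIGHT or reg == IPSI or reg == CONTRA:
            # cylindrical side wall
            a = uy * uy + uz * uz
            if a > 0.0:
                b = 2.0 * (y * uy + z * uz)
                c = y * y + z * z - R2
                tc = 2.0
                if c >= -_EPS2 and b > 0.0:
                    tc = 0.0
                else:
                    disc = b * b - 4.0 * a * c
                    if disc > 0.0:
                        tc = (-b + np.sqrt(disc)) / (2.0 * a)
                if -1e-9 <= tc <= 1.0 and tc < t_hit:
                    t_hit = tc
                    kind = 0
            # axial planes of this tube
            if mode == STRAIGHT:
                xl = 0.0
                kl = 1
                xr = xab
                kr = 6
            elif reg == IPSI:
                xl = 0.0
                kl = 1
                xr = xin
                kr = 2
            else:
                xl = xout
                kl = 2
                xr = xab
                kr = 6
            if ux < 0.0:
                tp = (xl - x) / ux
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = kl
                    plane_x = xl
            elif ux > 0.0:
                tp = (xr - x) / ux
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = kr
                    plane_x = xr
        else:
            # cavity: four side faces plus the two junction-bearing faces
            if uy > 0.0:
                tp = (half - y) / uy
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = 3
            elif uy < 0.0:
                tp = (-half - y) / uy
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = 3
            if uz > 0.0:
                tp = (half - z) / uz
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = 4
            elif uz < 0.0:
                tp = (-half - z) / uz
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    t_hit = tp
                    kind = 4
            if ux < 0.0:
                tp = (xin - x) / ux
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    yh = y + tp * uy
                    zh = z + tp * uz
                    if yh * yh + zh * zh <= R2 + _EPS2:
                        kind = 2
                    else:
                        kind = 1
                    t_hit = tp
                    plane_x = xin
            elif ux > 0.0:
                tp = (xout - x) / ux
                if -1e-9 <= tp <= 1.0 and tp < t_hit:
                    yh = y + tp * uy
                    zh = z + tp * uz
                    if yh * yh + zh * zh <= R2 + _EPS2:
                        kind = 2
                    else:
                        kind = 1
                    t_hit = tp
                    plane_x = xout

        if kind == -1:
            # endpoint lies inside the current region
            return x + ux, y + uy, z + uz, False, nrefl, False

        t = t_hit if t_hit > 0.0 else 0.0
        x += t * ux
        y += t * uy
        z += t * uz
        rem = 1.0 - t
        ux *= rem
        uy *= rem
        uz *= rem

        if kind == 6:
            return plane_x, y, z, True, nrefl, False
        if kind == 2:
            x = plane_x  # snap onto the junction plane and keep tracing
            continue

        nrefl += 1
        if nrefl > MAX_REFLECTIONS:
            return x0, y0, z0, False, nrefl, True

        if kind == 0:
            rn = np.sqrt(y * y + z * z)
            if rn > 0.0:
                ny = y / rn
                nz = z / rn
                dot = uy * ny + uz * nz
                uy -= 2.0 * dot * ny
                uz -= 2.0 * dot * nz
                # land a hair inside the wall to keep membership robust
                y = ny * R * (1.0 - 1e-12)
                z = nz * R * (1.0 - 1e-12)
        elif kind == 1:
            x = plane_x
            ux = -ux
        elif kind == 3:
            uy = -uy
        elif kind == 4:
            uz = -uz

    # event budget exhausted: the point sits on a boundary, which is inside
    return x, y, z, False, nrefl, False


@njit(cache=True, fastmath=True)
def _pair_forces(xs, ys, zs, alive, Fp, kq2, cutoff, soft, order):
    """Softened Coulomb repulsion, x-sorted sweep over gathered arrays.

    ``xs/ys/zs/alive`` are contiguous per-active-slot arrays; ``order``
    sorts the slots by x.  ``Fp`` (M,3) is overwritten.
    """
    M = xs.shape[0]
    s2 = soft * soft
    c2 = cutoff * cutoff
    for j in range(M):
        Fp[j, 0] = 0.0
        Fp[j, 1] = 0.0
        Fp[j, 2] = 0.0
    for a in range(M):
        j = order[a]
        if not alive[j]:
            continue
        xj = xs[j]
        yj = ys[j]
        zj = zs[j]
        for b in range(a + 1, M):
            k = order[b]
            if not alive[k]:
                continue
            dx = xj - xs[k]
            if -dx > cutoff:
                break
            dy = yj - ys[k]
            dz = zj - zs[k]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > c2:
                continue
            rs2 = r2 + s2
            w = kq2 / (rs2 * np.sqrt(rs2))
            fx = w * dx
            fy = w * dy
            fz = w * dz
            Fp[j, 0] += fx
            Fp[j, 1] += fy
            Fp[j, 2] += fz
            Fp[k, 0] -= fx
            Fp[k, 1] -= fy
            Fp[k, 2] -= fz


@njit(cache=True, fastmath=True)
def run_interval(mode, R, xin, xout, xab, half,
                 pos, status, abs_time,
                 idx, normals,
                 D, mu, fx, fy, fz,
                 inter_on, kq2, cutoff, soft,
                 dt_base, step_cap, t_start, t_stop):
    """Synchronized Euler-Maruyama stepping from t_start toward t_stop.

    Consumes one row of ``normals`` (K, M, 3) per step; returns early when
    the rows run out, when t_stop is reached, or when every particle in
    ``idx`` has been absorbed.  Pairwise forces are refreshed on an
    adaptive cadence (every step while the deterministic drift they cause
    is a significant fraction of ``step_cap``, up to every 8 steps when
    it is small), and the step size shrinks whenever the largest total
    drift would exceed ``step_cap``.

    Returns ``(t_reached, rows_used, n_reflections, n_fallback, all_absorbed)``.
    """
    M = idx.shape[0]
    K = normals.shape[0]
    t = t_start
    nref = 0
    nfall = 0
    Fp = np.zeros((M, 3))
    xs = np.empty(M)
    ys = np.empty(M)
    zs = np.empty(M)
    alive = np.empty(M, np.bool_)
    use_pairs = inter_on and kq2 > 0.0
    order = np.arange(M)
    fmax = 0.0
    row = 0
    while t < t_stop - 1e-12 and row < K:
        n_act = 0
        for j in range(M):
            alive[j] = status[idx[j]] == 0
            if alive[j]:
                n_act += 1
        if n_act == 0:
            return t, row, nref, nfall, True

        if use_pairs:
            for j in range(M):
                i = idx[j]
                xs[j] = pos[i, 0] if alive[j] else 1e30
                ys[j] = pos[i, 1]
                zs[j] = pos[i, 2]
            if row == 0:
                order[:] = np.argsort(xs)
            else:
                # positions move little per step: one insertion-sort pass
                # restores x-order in near-linear time
                for a in range(1, M):
                    j = order[a]
                    key = xs[j]
                    b = a - 1
                    while b >= 0 and xs[order[b]] > key:
                        order[b + 1] = order[b]
                        b -= 1
                    order[b + 1] = j
            _pair_forces(xs, ys, zs, alive, Fp, kq2, cutoff, soft, order)
            fmax2 = 0.0
            for j in range(M):
                if not alive[j]:
                    continue
                gx = fx + Fp[j, 0]
                gy = fy + Fp[j, 1]
                gz = fz + Fp[j, 2]
                m2 = gx * gx + gy * gy + gz * gz
                if m2 > fmax2:
                    fmax2 = m2
            fmax = np.sqrt(fmax2)

        dt = dt_base
        if t + dt > t_stop:
            dt = t_stop - t
        if use_pairs and mu > 0.0 and fmax > 0.0:
            dtf = step_cap / (mu * fmax)
            if dtf < dt:
                dt = dtf

        sq = np.sqrt(2.0 * D * dt)
        for j in range(M):
            i = idx[j]
            if status[i] != 0:
                continue
            gx = fx
            gy = fy
            gz = fz
            if use_pairs:
                gx += Fp[j, 0]
                gy += Fp[j, 1]
                gz += Fp[j, 2]
            ux = mu * gx * dt + sq * normals[row, j, 0]
            uy = mu * gy * dt + sq * normals[row, j, 1]
            uz = mu * gz * dt + sq * normals[row, j, 2]
            nx, ny, nz, absorbed, nr, fb = advance(
                mode, R, xin, xout, xab, half,
                pos[i, 0], pos[i, 1], pos[i, 2], ux, uy, uz)
            nref += nr
            if fb:
                nfall += 1
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
            if absorbed:
                status[i] = 1
                abs_time[i] = t + dt
        t += dt
        row += 1
    return t, row, nref, nfall, False


# ---------------------------------------------------------------------------
# Inline counter-based RNG (splitmix64 + polar Box-Muller).  The fast
# per-particle path draws a variable number of deviates per particle, so a
# self-contained generator with explicit state keeps runs bit-for-bit
# reproducible regardless of the host RNG implementation.

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_U53 = 1.0 / 9007199254740992.0


@njit(inline="always")
def _rand_u64(rs):
    rs[0] = rs[0] + _SM_GAMMA
    z = rs[0]
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _rand_uniform(rs):
    """Uniform double in [0, 1)."""
    return float(_rand_u64(rs) >> np.uint64(11)) * _U53


@njit(inline="always")
def _rand_normal(rs, nc):
    """Standard normal via the polar method with pair caching."""
    if nc[0] > 0.5:
        nc[0] = 0.0
        return nc[1]
    while True:
        u = 2.0 * _rand_uniform(rs) - 1.0
        v = 2.0 * _rand_uniform(rs) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            break
    f = np.sqrt(-2.0 * np.log(s) / s)
    nc[0] = 1.0
    nc[1] = v * f
    return u * f


@njit(inline="always")
def _rand_disk(rs, R):
    """Uniform point in the disk of radius R (rejection sampling)."""
    while True:
        y = R * (2.0 * _rand_uniform(rs) - 1.0)
        z = R * (2.0 * _rand_uniform(rs) - 1.0)
        if y * y + z * z <= R * R:
            return y, z


@njit(cache=True, fastmath=True)
def run_free(mode, R, xin, xout, xab, half,
             pos, status, abs_time,
             D, mu, fx, fy, fz,
             dt_fixed, dt_max, t_start, t_stop,
             seed_lo, seed_hi,
             sigma_tube_ipsi, sigma_tube_contra, sigma_min, sigma_cav_max,
             use_axial):
    """Per-particle stepping for non-interacting ensembles.

    Inside a tube the transverse coordinates decouple exactly from the
    axial ones (radial reflections preserve x; junction and absorbing
    events span the full cross-section), so the walker advances as a 1-D
    axial process with step ``sigma_tube_*``; its transverse position is
    frozen during the visit and redrawn from the uniform-disk equilibrium
    only when the visit outlasts the transverse mixing time R^2/D.  Exits
    keep their axial overshoot past the mouth plane.  In the cavity the
    walker takes full 3-D steps whose size grows with the distance to the
    nearest face (exact Brownian sampling; ``sigma_min`` resolution is
    kept near every boundary).  ``dt_fixed > 0`` switches to plain
    fixed-step 3-D Euler-Maruyama moves; ``use_axial=False`` keeps 3-D
    stepping (at ``sigma_min``) inside the tubes as well.

    The RNG state is derived from (seed_lo, seed_hi, particle index), so
    results do not depend on how [t_start, t_stop) is split into calls.

    Returns ``(n_moves, n_reflections, n_fallback)``.
    """
    n = pos.shape[0]
    moves = 0
    nref = 0
    nfall = 0
    fmag = np.sqrt(fx * fx + fy * fy + fz * fz)
    R2 = R * R
    t_mix = R * R / D if D > 0.0 else 1e300
    rs = np.empty(1, np.uint64)
    nc = np.zeros(2)
    for i in range(n):
        if status[i] != 0:
            continue
        # per-particle stream: mix the run seed, the particle index, and
        # the interval start time (so split calls never reuse deviates)
        rs[0] = ((np.uint64(seed_lo) + np.uint64(seed_hi) * np.uint64(2654435761)
                  + np.uint64(i) * np.uint64(0x9E3779B97F4A7C15))
                 ^ (np.uint64(t_start * 1048576.0) * np.uint64(0xD1B54A32D192ED03)))
        rs[0] = _rand_u64(rs)  # decorrelate nearby seeds
        nc[0] = 0.0
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        t = t_start
        tube_enter = t_start
        was_axial = False
        while t < t_stop - 1e-12:
            axial = False
            if dt_fixed > 0.0:
                sigma = sigma_min
            elif mode == STRAIGHT:
                axial = True
                d = xab - x  # absorbing plane is the only biasing feature
                sigma = 0.2 * d
                if sigma > sigma_tube_ipsi:
                    sigma = sigma_tube_ipsi
                if sigma < sigma_min:
                    sigma = sigma_min
                xlo = 0.0
                xhi = xab
                absorb_hi = True
                reflect_lo = True
            elif x < xin - _EPS and y * y + z * z <= R2 + _EPS2:
                axial = True
                d = xin - x  # resolve the mouth; x = 0 mirror is exact
                sigma = 0.2 * d
                if sigma > sigma_tube_ipsi:
                    sigma = sigma_tube_ipsi
                if sigma < sigma_min:
                    sigma = sigma_min
                xlo = 0.0
                xhi = xin
                absorb_hi = False
                reflect_lo = True
            elif x > xout + _EPS and y * y + z * z <= R2 + _EPS2:
                axial = True
                d = x - xout  # resolve both the mouth and the absorber
                d2 = xab - x
                if d2 < d:
                    d = d2
                sigma = 0.2 * d
                if sigma > sigma_tube_contra:
                    sigma = sigma_tube_contra
                if sigma < sigma_min:
                    sigma = sigma_min
                xlo = xout
                xhi = xab
                absorb_hi = True
                reflect_lo = False
            else:
                # Specular folding off the flat cavity faces is exact at any
                # step size (reflection principle), so only the two mouth
                # disks need fine resolution: grow the step with the
                # distance to the nearest mouth.
                rr = np.sqrt(y * y + z * z) - R
                if rr < 0.0:
                    rr = 0.0
                dxm = x - xin
                if dxm < 0.0:
                    dxm = -dxm
                d = np.sqrt(rr * rr + dxm * dxm)
                dxm = xout - x
                if dxm < 0.0:
                    dxm = -dxm
                d2 = np.sqrt(rr * rr + dxm * dxm)
                if d2 < d:
                    d = d2
                sigma = 0.2 * d
                if sigma > sigma_cav_max:
                    sigma = sigma_cav_max
                if sigma < sigma_min:
                    sigma = sigma_min
            if axial and not use_axial:
                axial = False
                sigma = sigma_min
            if axial and not was_axial:
                tube_enter = t
            was_axial = axial

            if dt_fixed > 0.0:
                dt = dt_fixed
            else:
                dt = sigma * sigma / (2.0 * D) if D > 0.0 else dt_max
                if dt > dt_max:
                    dt = dt_max
                if fmag > 0.0 and mu > 0.0:
                    dtf = sigma / (mu * fmag)
                    if dtf < dt:
                        dt = dtf
            if t + dt > t_stop:
                dt = t_stop - t
            sq = np.sqrt(2.0 * D * dt)
            moves += 1

            if axial:
                xn = x + mu * fx * dt + sq * _rand_normal(rs, nc)
                if reflect_lo and xn < xlo:
                    xn = 2.0 * xlo - xn
                    if xn < xlo:
                        xn = xlo
                t += dt
                if xn >= xhi:
                    if absorb_hi:
                        status[i] = 1
                        abs_time[i] = t
                        x = xab
                        break
                    # exit through the mouth, keeping the axial overshoot;
                    # redraw the transverse position only if the visit
                    # outlasted the transverse mixing time
                    x = xn if xn < xhi + 0.45 * half else xhi + 0.45 * half
                    if t - tube_enter > t_mix:
                        y, z = _rand_disk(rs, R)
                elif (not reflect_lo) and xn <= xlo:
                    x = xn if xn > xlo - 0.45 * half else xlo - 0.45 * half
                    if t - tube_enter > t_mix:
                        y, z = _rand_disk(rs, R)
                else:
                    x = xn
            else:
                ux = mu * fx * dt + sq * _rand_normal(rs, nc)
                uy = mu * fy * dt + sq * _rand_normal(rs, nc)
                uz = mu * fz * dt + sq * _rand_normal(rs, nc)
                nx, ny, nz, absorbed, nr, fb = advance(
                    mode, R, xin, xout, xab, half, x, y, z, ux, uy, uz)
                nref += nr
                if fb:
                    nfall += 1
                x = nx
                y = ny
                z = nz
                t += dt
                if absorbed:
                    status[i] = 1
                    abs_time[i] = t
                    break
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
    return moves, nref, nfall
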