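"""Numba kernel for time-resolved voxelized photon-packet transport.

One serial JIT routine advances every packet from launch to termination:

* free paths span voxels — an optical-depth budget ``-ln(xi)`` is consumed
  at the local extinction rate ``mu_t = mu_a + mu_s`` voxel by voxel, using
  exact axis-plane crossing distances;
* at an interaction the packet deposits ``w * mu_a / mu_t`` and scatters
  into a Henyey-Greenstein direction;
* voxels with ``mu_s = 0`` (clear media) attenuate continuously via
  Beer-Lambert along the ray instead of hosting discrete events, which is
  exact and keeps the discrete scheme where it is defined;
* refractive-index mismatches (the air interface by default) apply
  unpolarized Fresnel reflection / Snell refraction with a binary survival
  draw;
* per-tissue partial paths, visited-layer bits, elapsed time
  (``sum s_i n_i / c``), voxel traversal segments and a conservation ledger
  are tracked throughout.

Randomness is a per-photon splitmix64 counter stream derived from
``(seed, photon index)``, so results are bit-identical however photons are
batched.  The grid exterior is air; every escape is a surface event.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Speed of light in vacuum, mm/ps.
C_MM_PS = 0.299792458

#: Boundary nudge (mm) applied when stepping across a voxel face.
BOUNDARY_EPS = 1e-9

#: Launch nudge (mm) into the first tissue voxel.
LAUNCH_EPS = 1e-6

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_STREAM = _U64(0xA0761D6478BD642F)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# conservation-ledger slots
LEDGER_DEPOSITED = 0
LEDGER_EXIT_DETECTED = 1
LEDGER_EXIT_UNDETECTED = 2
LEDGER_TIME_GATED = 3
LEDGER_ROULETTE_NET = 4
LEDGER_SIZE = 5


@njit(inline="always", cache=True)
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@njit(inline="always", cache=True)
def _photon_state(seed, photon_idx):
    return _mix64(_U64(seed) ^ (_STREAM * (_U64(photon_idx) + _U64(1))))


@njit(inline="always", cache=True)
def _next_uniform(state):
    """Advance the splitmix64 stream; return (state, u) with u in [0, 1)."""
    state = state + _GAMMA
    z = _mix64(state)
    return state, float(z >> _U64(11)) * _INV53


@njit(inline="always", cache=True)
def _hg_cos_theta(u, g):
    """Inverse-CDF sample of cos(theta) from the Henyey-Greenstein density."""
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(inline="always", cache=True)
def _rotate_direction(ux, uy, uz, cos_t, psi):
    """Rotate a unit vector by polar angle theta and azimuth psi (local frame)."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(psi)
    sp = math.sin(psi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz >= 0.0 else -1.0
        nx, ny, nz = sin_t * cp, sin_t * sp, cos_t * sign
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
        ny = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
        nz = -sin_t * cp * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(inline="always", cache=True)
def _fresnel_unpolarized(cos_i, n_in, n_out):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns ``(R, cos_t)``; total internal reflection yields ``(1, 0)``.
    """
    if n_in == n_out:
        return 0.0, cos_i
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = ((n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)) ** 2
    rp = ((n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)) ** 2
    return 0.5 * (rs + rp), cos_t


@njit(cache=True)
def run_kernel(
    labels,            # (nx, ny, nz) uint8, 0 = air
    hx, hy, hz,        # voxel edge lengths, mm
    mu_a, mu_s, g_hg, n_refr,   # per-code arrays, len 6
    src, sdir,         # source position (mm) and inward unit direction
    det, det_r,        # (ndet, 3) detector centres (mm), disk radius (mm)
    n_photons, seed,
    gate_ps,
    roulette_on, r_thresh, r_surv,
    absorption,        # (nx, ny, nz) float64, deposited weight
    fl_bin_ps, fluence,       # time-binned traversal weight (nb, nx, ny, nz) f4
    ssp_slot, ssp,            # detector -> slot (-1 = off); (nslot, nx*ny*nz) f4
    paths_on, path_vox, path_len, path_ptr,  # CSR traversal log, detected only
    rec_det, rec_w, rec_t, rec_path, rec_vis,  # detection records
    seg_vox, seg_len,  # scratch per-photon segment buffers
    ledger,            # float64[LEDGER_SIZE]
):
    nx, ny, nz = labels.shape
    ndet = det.shape[0]
    nb_fl = fluence.shape[0]
    fluence_on = fl_bin_ps > 0.0
    track_segs = paths_on or (ssp.shape[0] > 0)
    max_segs = seg_vox.shape[0]
    path_cap = path_vox.shape[0]
    n_detected = 0
    n_path_truncated = 0
    path_cursor = 0
    inv_c = 1.0 / C_MM_PS

    for ph in range(n_photons):
        state = _photon_state(seed, ph)
        px = src[0] + sdir[0] * LAUNCH_EPS
        py = src[1] + sdir[1] * LAUNCH_EPS
        pz = src[2] + sdir[2] * LAUNCH_EPS
        dx, dy, dz = sdir[0], sdir[1], sdir[2]
        w = 1.0
        t = 0.0
        visited = 0
        pp = np.zeros(6)
        nseg = 0
        seg_overflow = False
        alive = True

        while alive:
            state, u = _next_uniform(state)
            budget = -math.log(1.0 - u)
            while True:  # march the ray until interaction or exit
                ix = int(math.floor(px / hx))
                iy = int(math.floor(py / hy))
                iz = int(math.floor(pz / hz))
                if (ix < 0 or ix >= nx or iy < 0 or iy >= ny
                        or iz < 0 or iz >= nz or labels[ix, iy, iz] == 0):
                    # safety net: packet already in air without an exit event
                    ledger[LEDGER_EXIT_UNDETECTED] += w
                    alive = False
                    break
                lbl = labels[ix, iy, iz]
                mua = mu_a[lbl]
                mus = mu_s[lbl]
                mut = mua + mus
                # exact distances to the next axis planes
                if dx > 0.0:
                    tx = ((ix + 1) * hx - px) / dx
                elif dx < 0.0:
                    tx = (ix * hx - px) / dx
                else:
                    tx = 1e30
                if dy > 0.0:
                    ty = ((iy + 1) * hy - py) / dy
                elif dy < 0.0:
                    ty = (iy * hy - py) / dy
                else:
                    ty = 1e30
                if dz > 0.0:
                    tz = ((iz + 1) * hz - pz) / dz
                elif dz < 0.0:
                    tz = (iz * hz - pz) / dz
                else:
                    tz = 1e30
                dbound = tx
                kaxis = 0
                if ty < dbound:
                    dbound = ty
                    kaxis = 1
                if tz < dbound:
                    dbound = tz
                    kaxis = 2
                if dbound < 0.0:
                    dbound = 0.0

                interacting = mus > 0.0 and mut * dbound >= budget
                s = budget / mut if interacting else dbound
                if not interacting:
                    if mus > 0.0:
                        budget -= mut * s
                    elif mua > 0.0 and s > 0.0:
                        # clear medium: continuous Beer-Lambert attenuation
                        trans = math.exp(-mua * s)
                        dep = w * (1.0 - trans)
                        absorption[ix, iy, iz] += dep
                        ledger[LEDGER_DEPOSITED] += dep
                        w *= trans
                px += dx * s
                py += dy * s
                pz += dz * s
                t += s * n_refr[lbl] * inv_c
                visited |= 1 << lbl
                pp[lbl] += s
                if track_segs and s > 0.0:
                    if nseg < max_segs:
                        seg_vox[nseg] = (ix * ny + iy) * nz + iz
                        seg_len[nseg] = s
                        nseg += 1
                    else:
                        seg_overflow = True
                if fluence_on and s > 0.0:
                    b = int(t / fl_bin_ps)
                    if b < nb_fl:
                        fluence[b, ix, iy, iz] += w * s

                if interacting:
                    dw = w * mua / mut
                    absorption[ix, iy, iz] += dw
                    ledger[LEDGER_DEPOSITED] += dw
                    w -= dw
                    state, u1 = _next_uniform(state)
                    state, u2 = _next_uniform(state)
                    cos_t = _hg_cos_theta(u1, g_hg[lbl])
                    psi = 2.0 * math.pi * u2
                    dx, dy, dz = _rotate_direction(dx, dy, dz, cos_t, psi)
                    if t > gate_ps:
                        ledger[LEDGER_TIME_GATED] += w
                        alive = False
                    elif roulette_on and w < r_thresh:
                        state, u = _next_uniform(state)
                        if u < r_surv:
                            boost = w * (1.0 / r_surv - 1.0)
                            ledger[LEDGER_ROULETTE_NET] -= boost
                            w += boost
                        else:
                            ledger[LEDGER_ROULETTE_NET] += w
                            alive = False
                    break  # redraw budget

                # at a voxel face
                if t > gate_ps:
                    ledger[LEDGER_TIME_GATED] += w
                    alive = False
                    break
                jx, jy, jz = ix, iy, iz
                if kaxis == 0:
                    sgn = 1.0 if dx > 0.0 else -1.0
                    jx += 1 if dx > 0.0 else -1
                    dk = dx
                elif kaxis == 1:
                    sgn = 1.0 if dy > 0.0 else -1.0
                    jy += 1 if dy > 0.0 else -1
                    dk = dy
                else:
                    sgn = 1.0 if dz > 0.0 else -1.0
                    jz += 1 if dz > 0.0 else -1
                    dk = dz
                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    nb_lbl = 0
                else:
                    nb_lbl = int(labels[jx, jy, jz])
                n1 = n_refr[lbl]
                n2 = n_refr[nb_lbl]

                if n1 != n2:
                    cos_i = abs(dk)
                    refl, cos_t2 = _fresnel_unpolarized(cos_i, n1, n2)
                    if refl >= 1.0:
                        do_reflect = True  # total internal reflection
                    elif refl > 0.0:
                        state, u = _next_uniform(state)
                        do_reflect = u < refl
                    else:
                        do_reflect = False
                    if do_reflect:
                        if kaxis == 0:
                            dx = -dx
                            px -= sgn * BOUNDARY_EPS
                        elif kaxis == 1:
                            dy = -dy
                            py -= sgn * BOUNDARY_EPS
                        else:
                            dz = -dz
                            pz -= sgn * BOUNDARY_EPS
                        continue
                    if nb_lbl != 0:
                        # refraction between index-mismatched tissues:
                        # d' = eta*d + (eta*cos_i - cos_t)*n, n = -sgn along k
                        eta = n1 / n2
                        scale = eta * cos_i - cos_t2
                        dx *= eta
                        dy *= eta
                        dz *= eta
                        if kaxis == 0:
                            dx = eta * dk - scale * sgn
                        elif kaxis == 1:
                            dy = eta * dk - scale * sgn
                        else:
                            dz = eta * dk - scale * sgn
                        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                        dx /= norm
                        dy /= norm
                        dz /= norm

                if nb_lbl == 0:
                    # exit into air at the face position (px, py, pz)
                    det_hit = -1
                    for d in range(ndet):
                        ddx = px - det[d, 0]
                        ddy = py - det[d, 1]
                        ddz = pz - det[d, 2]
                        if ddx * ddx + ddy * ddy + ddz * ddz <= det_r * det_r:
                            det_hit = d
                            break
                    if det_hit >= 0:
                        ledger[LEDGER_EXIT_DETECTED] += w
                        rec_det[n_detected] = det_hit
                        rec_w[n_detected] = w
                        rec_t[n_detected] = t
                        for c in range(6):
                            rec_path[n_detected, c] = pp[c]
                        rec_vis[n_detected] = visited
                        slot = ssp_slot[det_hit]
                        if slot >= 0:
                            for si in range(nseg):
                                ssp[slot, seg_vox[si]] += w * seg_len[si]
                        if paths_on:
                            if not seg_overflow and path_cursor + nseg <= path_cap:
                                for si in range(nseg):
                                    path_vox[path_cursor + si] = seg_vox[si]
                                    path_len[path_cursor + si] = seg_len[si]
                                path_cursor += nseg
                            else:
                                n_path_truncated += 1
                            path_ptr[n_detected + 1] = path_cursor
                        n_detected += 1
                    else:
                        ledger[LEDGER_EXIT_UNDETECTED] += w
                    alive = False
                    break

                # step across the face and keep marching
                if kaxis == 0:
                    px += sgn * BOUNDARY_EPS
                elif kaxis == 1:
                    py += sgn * BOUNDARY_EPS
                else:
                    pz += sgn * BOUNDARY_EPS

    return n_detected, path_cursor, n_path_truncated
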