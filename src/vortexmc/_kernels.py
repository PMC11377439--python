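"""Numba kernels for the photon random walk.

Scalar, single-threaded routines compiled with numba so that the Python
API modules (`medium`, `engine`) and the batched transport loop share one
implementation of the scattering rotation, the Henyey-Greenstein inversion
and the polarization-resolved Fresnel split.

Phase bookkeeping: the propagation phase decreases by k*n*l per segment,
matching the exp(-ikz) convention of the analytic mode, so the ballistic
limit reproduces the free-space phase evolution exactly.
"""

import math

import numpy as np
from numba import njit

_INF = 1e300

# xoshiro256+ inline generator: the transport loop draws ~10^9 uniforms per
# run and the generator state lives in registers, which roughly halves the
# per-event cost relative to the boxed Mersenne Twister
_U64 = np.uint64
_SPLITMIX_GAMMA = _U64(0x9E3779B97F4A7C15)
_SPLITMIX_M1 = _U64(0xBF58476D1CE4E5B9)
_SPLITMIX_M2 = _U64(0x94D049BB133111EB)
_DBL_NORM = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(state):
    state = state + _SPLITMIX_GAMMA
    z = state
    z = (z ^ (z >> _U64(30))) * _SPLITMIX_M1
    z = (z ^ (z >> _U64(27))) * _SPLITMIX_M2
    z = z ^ (z >> _U64(31))
    return state, z


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << k) | (x >> (_U64(64) - k))


@njit(cache=True, inline="always")
def _rng_next(s0, s1, s2, s3):
    """One xoshiro256+ step; returns a uniform double in [0, 1)."""
    result = s0 + s3
    t = s1 << _U64(17)
    s2 = s2 ^ s0
    s3 = s3 ^ s1
    s1 = s1 ^ s2
    s0 = s0 ^ s3
    s2 = s2 ^ t
    s3 = _rotl(s3, _U64(45))
    return float(result >> _U64(11)) * _DBL_NORM, s0, s1, s2, s3


@njit(cache=True)
def _rng_seed(seed):
    """Expand a 32/64-bit seed into a full xoshiro256+ state via splitmix64."""
    st = _U64(seed)
    st, s0 = _splitmix64(st)
    st, s1 = _splitmix64(st)
    st, s2 = _splitmix64(st)
    st, s3 = _splitmix64(st)
    return s0, s1, s2, s3


@njit(cache=True, fastmath=True)
def hg_invert(g, xi):
    """Closed-form inverse CDF of the HG phase function; xi in (0, 1]."""
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True)
def rotate_direction(sx, sy, sz, cos_t, az):
    """Rotate a unit vector by polar angle acos(cos_t), azimuth az, in its local frame.

    Standard scattering rotation with the singularity guard for |sz| ~ 1.
    """
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(az)
    sp = math.sin(az)
    if abs(sz) > 1.0 - 1e-12:
        sgn = 1.0 if sz >= 0.0 else -1.0
        nx = sin_t * cp
        ny = sin_t * sp * sgn
        nz = cos_t * sgn
    else:
        den = math.sqrt(1.0 - sz * sz)
        nx = sin_t * (sx * sz * cp - sy * sp) / den + sx * cos_t
        ny = sin_t * (sy * sz * cp + sx * sp) / den + sy * cos_t
        nz = -den * sin_t * cp + sz * cos_t
    nrm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nrm, ny / nrm, nz / nrm


@njit(cache=True)
def boundary_event(dx, dy, dz, nx, ny, nz, n1, n2,
                   pxx, pxy, pxz, pyx, pyy, pyz):
    """Snell/Fresnel interaction of a photon with a plane interface.

    The surface normal (nx,ny,nz) must point into medium 2 (d . n > 0).
    Returns
    -------
    (tir, T, tdx,tdy,tdz, rdx,rdy,rdz,
     tpxx,tpxy,tpxz, tpyx,tpyy,tpyz,
     rpxx,rpxy,rpxz, rpyx,rpyy,rpyz)
    where transmitted polarization vectors include the sqrt(n2 ct/(n1 ci))
    power factor so |P_t|^2 + |P_r|^2 = |P|^2 per vector, and T is the power
    transmittance of the current polarization pair (unpolarized average when
    the pair is null).
    """
    ci = dx * nx + dy * ny + dz * nz
    sin_i2 = max(0.0, 1.0 - ci * ci)
    eta = n1 / n2
    sin_t2 = eta * eta * sin_i2
    rdx = dx - 2.0 * ci * nx
    rdy = dy - 2.0 * ci * ny
    rdz = dz - 2.0 * ci * nz
    if sin_t2 >= 1.0:
        # total internal reflection: |r| = 1 for both components (the TIR
        # phase shift is not representable with real P vectors); the s/p
        # frame is always well defined here since the incidence is oblique
        cxx = dy * nz - dz * ny
        cxy = dz * nx - dx * nz
        cxz = dx * ny - dy * nx
        cn = math.sqrt(cxx * cxx + cxy * cxy + cxz * cxz)
        shx = cxx / cn
        shy = cxy / cn
        shz = cxz / cn
        pix = shy * dz - shz * dy
        piy = shz * dx - shx * dz
        piz = shx * dy - shy * dx
        prx = shy * rdz - shz * rdy
        pry = shz * rdx - shx * rdz
        prz = shx * rdy - shy * rdx
        asx = pxx * shx + pxy * shy + pxz * shz
        apx = pxx * pix + pxy * piy + pxz * piz
        asy = pyx * shx + pyy * shy + pyz * shz
        apy = pyx * pix + pyy * piy + pyz * piz
        return (1, 0.0, 0.0, 0.0, 0.0, rdx, rdy, rdz,
                0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                asx * shx + apx * prx, asx * shy + apx * pry, asx * shz + apx * prz,
                asy * shx + apy * prx, asy * shy + apy * pry, asy * shz + apy * prz)
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n2 * ci - n1 * ct) / (n2 * ci + n1 * ct)
    ts = 2.0 * n1 * ci / (n1 * ci + n2 * ct)
    tp = 2.0 * n1 * ci / (n2 * ci + n1 * ct)
    tdx = eta * dx + (ct - eta * ci) * nx
    tdy = eta * dy + (ct - eta * ci) * ny
    tdz = eta * dz + (ct - eta * ci) * nz
    tn = math.sqrt(tdx * tdx + tdy * tdy + tdz * tdz)
    tdx /= tn
    tdy /= tn
    tdz /= tn
    pf = math.sqrt((n2 * ct) / (n1 * ci))

    # s-hat = d x n / |d x n|; degenerate at normal incidence
    cxx = dy * nz - dz * ny
    cxy = dz * nx - dx * nz
    cxz = dx * ny - dy * nx
    cn = math.sqrt(cxx * cxx + cxy * cxy + cxz * cxz)
    if cn < 1e-9:
        # normal incidence: s/p coefficients coincide (|rs| = |rp|); reuse
        # the incoming polarization frame directly
        tpxx = ts * pf * pxx
        tpxy = ts * pf * pxy
        tpxz = ts * pf * pxz
        tpyx = ts * pf * pyx
        tpyy = ts * pf * pyy
        tpyz = ts * pf * pyz
        rpxx = rs * pxx
        rpxy = rs * pxy
        rpxz = rs * pxz
        rpyx = rs * pyx
        rpyy = rs * pyy
        rpyz = rs * pyz
    else:
        shx = cxx / cn
        shy = cxy / cn
        shz = cxz / cn
        # p-hat(incident) = s-hat x d; p-hat(trans/refl) likewise
        pix = shy * dz - shz * dy
        piy = shz * dx - shx * dz
        piz = shx * dy - shy * dx
        ptx = shy * tdz - shz * tdy
        pty = shz * tdx - shx * tdz
        ptz = shx * tdy - shy * tdx
        prx = shy * rdz - shz * rdy
        pry = shz * rdx - shx * rdz
        prz = shx * rdy - shy * rdx
        asx = pxx * shx + pxy * shy + pxz * shz
        apx = pxx * pix + pxy * piy + pxz * piz
        asy = pyx * shx + pyy * shy + pyz * shz
        apy = pyx * pix + pyy * piy + pyz * piz
        tpxx = pf * (ts * asx * shx + tp * apx * ptx)
        tpxy = pf * (ts * asx * shy + tp * apx * pty)
        tpxz = pf * (ts * asx * shz + tp * apx * ptz)
        tpyx = pf * (ts * asy * shx + tp * apy * ptx)
        tpyy = pf * (ts * asy * shy + tp * apy * pty)
        tpyz = pf * (ts * asy * shz + tp * apy * ptz)
        rpxx = rs * asx * shx + rp * apx * prx
        rpxy = rs * asx * shy + rp * apx * pry
        rpxz = rs * asx * shz + rp * apx * prz
        rpyx = rs * asy * shx + rp * apy * prx
        rpyy = rs * asy * shy + rp * apy * pry
        rpyz = rs * asy * shz + rp * apy * prz

    s0 = pxx * pxx + pxy * pxy + pxz * pxz + pyx * pyx + pyy * pyy + pyz * pyz
    if s0 > 0.0:
        st = (tpxx * tpxx + tpxy * tpxy + tpxz * tpxz
              + tpyx * tpyx + tpyy * tpyy + tpyz * tpyz)
        T = st / s0
    else:
        T = 1.0 - 0.5 * (rs * rs + rp * rp)
    if T > 1.0:
        T = 1.0
    return (0, T, tdx, tdy, tdz, rdx, rdy, rdz,
            tpxx, tpxy, tpxz, tpyx, tpyy, tpyz,
            rpxx, rpxy, rpxz, rpyx, rpyy, rpyz)


@njit(cache=True, fastmath=True)
def transport_loop(x0, y0, psi0, dirs, polx, poly, w0,
                   k0, mus, mua, g, n_med, n_amb, thickness, gamma_r,
                   floor_w, max_events,
                   r_d, cos_na, sdet, det_at_exit, apply_exit_fresnel,
                   quota, seed,
                   out_x, out_y, out_s, out_psi,
                   out_w, out_wpar, out_wperp, out_nev):
    """Random-walk a batch of source photons through the slab.

    Boundary interactions use probabilistic branch selection with the
    polarization pair renormalized across the interface (unbiased in
    expectation); the detection weight and its polarized/depolarized parts
    are evaluated from the transverse components of the polarization pair.
    For the common Gamma_R = 1 case the Beer-Lambert factor is applied
    lazily from the accumulated path (one exp per boundary event instead
    of one per segment).  Returns the detection count plus the weight
    ledger (launched, entry_reflected, absorbed, exit_undetected,
    terminated_floor, terminated_cap, detected, gamma_loss).
    """
    rs0, rs1, rs2, rs3 = _rng_seed(seed)
    count = 0
    launched = 0
    w_launched = 0.0
    w_entry_refl = 0.0
    w_absorbed = 0.0
    w_exit_undet = 0.0
    w_floor = 0.0
    w_cap = 0.0
    w_detected = 0.0
    w_gamma = 0.0
    n_src = x0.shape[0]
    sdx, sdy, sdz = sdet[0], sdet[1], sdet[2]
    lazy = gamma_r == 1.0  # absorption applied from the path integral
    two_pi = 2.0 * np.pi

    for j in range(n_src):
        if count >= quota:
            break
        launched += 1
        W0j = w0[j]
        W = W0j
        w_launched += W0j
        dx = dirs[j, 0]
        dy = dirs[j, 1]
        dz = dirs[j, 2]
        pxx = polx[j, 0]
        pxy = polx[j, 1]
        pxz = polx[j, 2]
        pyx = poly[j, 0]
        pyy = poly[j, 1]
        pyz = poly[j, 2]
        phase = psi0[j]
        x = x0[j]
        y = y0[j]
        z = 0.0
        path = 0.0
        path_floor = _INF
        if lazy and mua > 0.0:
            path_floor = math.log(W0j / floor_w) / mua

        # entry interface: ambient -> medium through z = 0, normal +z
        if n_amb != n_med:
            res = boundary_event(dx, dy, dz, 0.0, 0.0, 1.0, n_amb, n_med,
                                 pxx, pxy, pxz, pyx, pyy, pyz)
            T = res[1]
            u, rs0, rs1, rs2, rs3 = _rng_next(rs0, rs1, rs2, rs3)
            if u < T:
                dx, dy, dz = res[2], res[3], res[4]
                s0 = (pxx * pxx + pxy * pxy + pxz * pxz
                      + pyx * pyx + pyy * pyy + pyz * pyz)
                st = (res[8] * res[8] + res[9] * res[9] + res[10] * res[10]
                      + res[11] * res[11] + res[12] * res[12] + res[13] * res[13])
                sc = math.sqrt(s0 / st) if st > 0.0 else 0.0
                pxx, pxy, pxz = res[8] * sc, res[9] * sc, res[10] * sc
                pyx, pyy, pyz = res[11] * sc, res[12] * sc, res[13] * sc
            else:
                w_entry_refl += W0j
                continue

        nev = 0
        alive = True
        while alive:
            if mus > 0.0:
                u, rs0, rs1, rs2, rs3 = _rng_next(rs0, rs1, rs2, rs3)
                l = -math.log(1.0 - u) / mus
            else:
                l = _INF
            if dz > 1e-300:
                t_face = (thickness - z) / dz
                face_up = True
            elif dz < -1e-300:
                t_face = -z / dz
                face_up = False
            else:
                t_face = _INF
                face_up = True

            if t_face <= l:
                # reach a slab face before the next scattering event
                x += dx * t_face
                y += dy * t_face
                z = thickness if face_up else 0.0
                phase -= k0 * n_med * t_face
                path += t_face
                if mua > 0.0:
                    if lazy:
                        Wn = W0j * math.exp(-mua * path)
                    else:
                        Wn = W * math.exp(-mua * t_face)
                    w_absorbed += W - Wn
                    W = Wn
                nzs = 1.0 if face_up else -1.0
                res = boundary_event(dx, dy, dz, 0.0, 0.0, nzs, n_med, n_amb,
                                     pxx, pxy, pxz, pyx, pyy, pyz)
                if not apply_exit_fresnel:
                    exits = True
                    edx, edy, edz = dx, dy, dz
                else:
                    u, rs0, rs1, rs2, rs3 = _rng_next(rs0, rs1, rs2, rs3)
                    exits = res[0] == 0 and u < res[1]
                    edx, edy, edz = res[2], res[3], res[4]
                if exits:
                    if apply_exit_fresnel:
                        s0 = (pxx * pxx + pxy * pxy + pxz * pxz
                              + pyx * pyx + pyy * pyy + pyz * pyz)
                        st = (res[8] * res[8] + res[9] * res[9] + res[10] * res[10]
                              + res[11] * res[11] + res[12] * res[12] + res[13] * res[13])
                        sc = math.sqrt(s0 / st) if st > 0.0 else 0.0
                        pxx, pxy, pxz = res[8] * sc, res[9] * sc, res[10] * sc
                        pyx, pyy, pyz = res[11] * sc, res[12] * sc, res[13] * sc
                    accepted = False
                    on_det_plane = face_up == det_at_exit
                    if on_det_plane and -r_d <= x <= r_d and -r_d <= y <= r_d:
                        ca = edx * sdx + edy * sdy + edz * sdz
                        if ca > cos_na:
                            accepted = True
                    if accepted and count < quota:
                        out_x[count] = x
                        out_y[count] = y
                        out_s[count, 0] = edx
                        out_s[count, 1] = edy
                        out_s[count, 2] = edz
                        out_psi[count] = phase
                        wpar = W * (pxx * pxx + pyx * pyx)
                        wperp = W * (pxy * pxy + pyy * pyy)
                        out_w[count] = wpar + wperp
                        out_wpar[count] = wpar
                        out_wperp[count] = wperp
                        out_nev[count] = nev
                        count += 1
                        w_detected += W
                    else:
                        w_exit_undet += W
                    alive = False
                else:
                    dx, dy, dz = res[5], res[6], res[7]
                    s0 = (pxx * pxx + pxy * pxy + pxz * pxz
                          + pyx * pyx + pyy * pyy + pyz * pyz)
                    st = (res[14] * res[14] + res[15] * res[15] + res[16] * res[16]
                          + res[17] * res[17] + res[18] * res[18] + res[19] * res[19])
                    sc = math.sqrt(s0 / st) if st > 0.0 else 0.0
                    pxx, pxy, pxz = res[14] * sc, res[15] * sc, res[16] * sc
                    pyx, pyy, pyz = res[17] * sc, res[18] * sc, res[19] * sc
            else:
                # interior scattering step
                x += dx * l
                y += dy * l
                z += dz * l
                phase -= k0 * n_med * l
                path += l
                if mua > 0.0 and not lazy:
                    Wn = W * math.exp(-mua * l)
                    w_absorbed += W - Wn
                    W = Wn
                nev += 1
                if nev > max_events:
                    if lazy and mua > 0.0:
                        Wn = W0j * math.exp(-mua * path)
                        w_absorbed += W - Wn
                        W = Wn
                    w_cap += W
                    alive = False
                    continue
                u, rs0, rs1, rs2, rs3 = _rng_next(rs0, rs1, rs2, rs3)
                cos_t = hg_invert(g, 1.0 - u)
                u, rs0, rs1, rs2, rs3 = _rng_next(rs0, rs1, rs2, rs3)
                az = two_pi * u
                dx, dy, dz = rotate_direction(dx, dy, dz, cos_t, az)
                q = pxx * dx + pxy * dy + pxz * dz
                pxx -= q * dx
                pxy -= q * dy
                pxz -= q * dz
                q = pyx * dx + pyy * dy + pyz * dz
                pyx -= q * dx
                pyy -= q * dy
                pyz -= q * dz
                if not lazy:
                    w_gamma += W * (1.0 - gamma_r)
                    W *= gamma_r
                    if W < floor_w:
                        w_floor += W
                        alive = False
                elif path > path_floor:
                    Wn = W0j * math.exp(-mua * path)
                    w_absorbed += W - Wn
                    w_floor += Wn
                    alive = False

    return (count, launched, w_launched, w_entry_refl, w_absorbed,
            w_exit_undet, w_floor, w_cap, w_detected, w_gamma)
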