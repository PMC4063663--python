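"""Numba kernels for the C-alpha structure-based model.

All quantities are in reduced units: lengths in nm, energies in epsilon,
k_B = 1, uniform bead mass, time in reduced time units. The hot loops
(forces, neighbor list, integrator) are jitted; the Python-facing wrappers
live in ``sbm.py`` and ``md.py``.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True, error_model="numpy")
def bonded_forces(x, bidx, br0, kb, aidx, at0, ka, didx, dp0c, dp0s, kd1, kd3, f):
    """Bond + angle + dihedral energies; forces accumulated into ``f``."""
    e_bond = 0.0
    for k in range(bidx.shape[0]):
        i = bidx[k, 0]
        j = bidx[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[k]
        e_bond += kb * dr * dr
        fac = -2.0 * kb * dr / r
        f[j, 0] += fac * dx
        f[j, 1] += fac * dy
        f[j, 2] += fac * dz
        f[i, 0] -= fac * dx
        f[i, 1] -= fac * dy
        f[i, 2] -= fac * dz

    e_angle = 0.0
    for k in range(aidx.shape[0]):
        i = aidx[k, 0]
        j = aidx[k, 1]
        l = aidx[k, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[l, 0] - x[j, 0]
        vy = x[l, 1] - x[j, 1]
        vz = x[l, 2] - x[j, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = math.acos(c)
        dth = th - at0[k]
        e_angle += ka * dth * dth
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = 2.0 * ka * dth / s
        # conservative wall at 170 deg: keeps the chain away from the
        # collinear region where the dihedral geometry degenerates
        if th > 2.9670597283903604:
            dwall = th - 2.9670597283903604
            e_angle += 10.0 * ka * dwall * dwall
            coef += 20.0 * ka * dwall / s
        # F_i = coef * (v_hat - c*u_hat)/nu ; F_l symmetric
        fix = coef * (vx / nv - c * ux / nu) / nu
        fiy = coef * (vy / nv - c * uy / nu) / nu
        fiz = coef * (vz / nv - c * uz / nu) / nu
        flx = coef * (ux / nu - c * vx / nv) / nv
        fly = coef * (uy / nu - c * vy / nv) / nv
        flz = coef * (uz / nu - c * vz / nv) / nv
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[l, 0] += flx
        f[l, 1] += fly
        f[l, 2] += flz
        f[j, 0] -= fix + flx
        f[j, 1] -= fiy + fly
        f[j, 2] -= fiz + flz

    e_dih = 0.0
    for k in range(didx.shape[0]):
        i = didx[k, 0]
        j = didx[k, 1]
        m = didx[k, 2]
        l = didx[k, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[m, 0] - x[j, 0]
        b2y = x[m, 1] - x[j, 1]
        b2z = x[m, 2] - x[j, 2]
        b3x = x[l, 0] - x[m, 0]
        b3y = x[l, 1] - x[m, 1]
        b3z = x[l, 2] - x[m, 2]
        # n1 = b1 x b2, n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        # clamp against grazing collinearity (sin^2 theta >= 1e-3) so the
        # torsional force stays bounded through rare straightened angles
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        b2sq = nb2 * nb2
        floor1 = 1e-3 * b1sq * b2sq
        floor2 = 1e-3 * b3sq * b2sq
        if n1sq < floor1:
            n1sq = floor1
        if n2sq < floor2:
            n2sq = floor2
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # cos/sin of phi from geometry, then angle addition with the
        # precomputed cos/sin of phi0 — no trig calls in the hot loop
        inv12 = 1.0 / math.sqrt(n1sq * n2sq)
        cphi = (n1x * n2x + n1y * n2y + n1z * n2z) * inv12
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sphi = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2 * inv12
        cd = cphi * dp0c[k] + sphi * dp0s[k]          # cos(phi - phi0)
        sd = sphi * dp0c[k] - cphi * dp0s[k]          # sin(phi - phi0)
        c3 = 4.0 * cd * cd * cd - 3.0 * cd            # cos 3(phi - phi0)
        s3 = 3.0 * sd - 4.0 * sd * sd * sd            # sin 3(phi - phi0)
        e_dih += kd1 * (1.0 - cd) + kd3 * (1.0 - c3)
        dEdphi = kd1 * sd + 3.0 * kd3 * s3
        fi = dEdphi * nb2 / n1sq
        fl = -dEdphi * nb2 / n2sq
        fix = fi * n1x
        fiy = fi * n1y
        fiz = fi * n1z
        flx = fl * n2x
        fly = fl * n2y
        flz = fl * n2z
        t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        t3 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        sjx = -t1 * fix + t3 * flx
        sjy = -t1 * fiy + t3 * fly
        sjz = -t1 * fiz + t3 * flz
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[l, 0] += flx
        f[l, 1] += fly
        f[l, 2] += flz
        f[j, 0] += -fix + sjx
        f[j, 1] += -fiy + sjy
        f[j, 2] += -fiz + sjz
        f[m, 0] += -flx - sjx
        f[m, 1] += -fly - sjy
        f[m, 2] += -flz - sjz

    return e_bond, e_angle, e_dih


@njit(cache=True, fastmath=True, error_model="numpy")
def contact_forces(x, cidx, cr0, ceps, sigma, width, f):
    """Gaussian-well native contacts with a hard (sigma/r)^12 core."""
    e = 0.0
    s12 = sigma ** 12
    w2 = width * width
    for k in range(cidx.shape[0]):
        i = cidx[k, 0]
        j = cidx[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        rep = s12 / (r2 * r2 * r2 * r2 * r2 * r2)
        dr = r - cr0[k]
        eps = ceps[k]
        if dr * dr > 72.0 * w2 and r > 1.5 * sigma:
            # far outside the well: the Gaussian underflows (< 1e-15),
            # only the excluded-volume tail remains
            e += eps * rep
            fac = 12.0 * eps * rep / r2
            f[j, 0] += fac * dx
            f[j, 1] += fac * dy
            f[j, 2] += fac * dz
            f[i, 0] -= fac * dx
            f[i, 1] -= fac * dy
            f[i, 2] -= fac * dz
            continue
        g = math.exp(-dr * dr / (2.0 * w2))
        e += eps * ((1.0 + rep) * (1.0 - g) - 1.0)
        # dV/dr
        dvdr = eps * (-12.0 * rep / r * (1.0 - g) + (1.0 + rep) * (dr / w2) * g)
        fac = -dvdr / r
        f[j, 0] += fac * dx
        f[j, 1] += fac * dy
        f[j, 2] += fac * dz
        f[i, 0] -= fac * dx
        f[i, 1] -= fac * dy
        f[i, 2] -= fac * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def repulsion_forces(x, pairs, npairs, sigma, eps_rep, rcut, f):
    """Truncated, force-shifted (sigma/r)^12 excluded volume.

    Both the potential and the force vanish continuously at ``rcut`` so
    cutoff crossings do not pump energy in microcanonical runs.
    """
    e = 0.0
    s12 = sigma ** 12
    rc2 = rcut * rcut
    vc = s12 / rcut ** 12
    fc = 12.0 * s12 / rcut ** 13          # |dV/dr| at the cutoff
    for k in range(npairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = math.sqrt(r2)
        rep = s12 / (r2 * r2 * r2 * r2 * r2 * r2)
        e += eps_rep * (rep - vc + fc * (r - rcut))
        fac = eps_rep * (12.0 * rep / r - fc) / r
        f[j, 0] += fac * dx
        f[j, 1] += fac * dy
        f[j, 2] += fac * dz
        f[i, 0] -= fac * dx
        f[i, 1] -= fac * dy
        f[i, 2] -= fac * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _xorshift128p(state):
    """xorshift128+ step returning a uint64."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return s0 + s1


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _uniform01(state):
    return (_xorshift128p(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _gauss_pair(state, out):
    """Marsaglia polar pair of standard normals into ``out[0:2]``."""
    while True:
        a = 2.0 * _uniform01(state) - 1.0
        b = 2.0 * _uniform01(state) - 1.0
        s = a * a + b * b
        if 0.0 < s < 1.0:
            fac = math.sqrt(-2.0 * math.log(s) / s)
            out[0] = a * fac
            out[1] = b * fac
            return


@njit(cache=True, error_model="numpy")
def build_pairs(x, n, rlist, excl_keys, pairs):
    """All-pairs neighbor list with |i-j| >= 4 and exclusion lookup.

    ``excl_keys`` is a sorted array of i*n+j codes (i < j) to skip
    (native contacts and the disulphide bond). Returns the pair count.
    """
    rl2 = rlist * rlist
    cnt = 0
    for i in range(n):
        for j in range(i + 4, n):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rl2:
                continue
            key = i * n + j
            lo = 0
            hi = excl_keys.shape[0]
            found = False
            while lo < hi:
                mid = (lo + hi) // 2
                v = excl_keys[mid]
                if v == key:
                    found = True
                    break
                elif v < key:
                    lo = mid + 1
                else:
                    hi = mid
            if found:
                continue
            if cnt < pairs.shape[0]:
                pairs[cnt, 0] = i
                pairs[cnt, 1] = j
            cnt += 1
    return cnt


@njit(cache=True, fastmath=True, error_model="numpy")
def smooth_q(x, cidx, cr0, lam, beta_w):
    """Differentiable native-contact fraction using logistic switches."""
    q = 0.0
    m = cidx.shape[0]
    for k in range(m):
        i = cidx[k, 0]
        j = cidx[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        w = beta_w * cr0[k]
        q += 1.0 / (1.0 + math.exp((r - lam * cr0[k]) / w))
    return q / m


@njit(cache=True, fastmath=True, error_model="numpy")
def smooth_q_forces(x, cidx, cr0, lam, beta_w, k_umb, q_center, f, s_buf):
    """Umbrella bias 0.5*k*(Qs - Qc)^2: energy returned, forces added.

    ``s_buf`` caches the logistic switch values so the exponential is
    evaluated once per contact per step.
    """
    m = cidx.shape[0]
    q = 0.0
    for k in range(m):
        i = cidx[k, 0]
        j = cidx[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        w = beta_w * cr0[k]
        s = 1.0 / (1.0 + math.exp((r - lam * cr0[k]) / w))
        s_buf[k] = s
        q += s
    q /= m
    pref = k_umb * (q - q_center) / m
    for k in range(m):
        i = cidx[k, 0]
        j = cidx[k, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        w = beta_w * cr0[k]
        s = s_buf[k]
        dsdr = -s * (1.0 - s) / w
        fac = -pref * dsdr / r
        f[j, 0] += fac * dx
        f[j, 1] += fac * dy
        f[j, 2] += fac * dz
        f[i, 0] -= fac * dx
        f[i, 1] -= fac * dy
        f[i, 2] -= fac * dz
    return 0.5 * k_umb * (q - q_center) * (q - q_center), q


@njit(cache=True, fastmath=True, error_model="numpy")
def compute_forces(
    x, f,
    bidx, br0, kb, aidx, at0, ka, didx, dp0c, dp0s, kd1, kd3,
    cidx, cr0, ceps, sigma, width,
    pairs, npairs, eps_rep, rcut,
):
    for i in range(f.shape[0]):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    eb, ea, ed = bonded_forces(x, bidx, br0, kb, aidx, at0, ka, didx,
                               dp0c, dp0s, kd1, kd3, f)
    ec = contact_forces(x, cidx, cr0, ceps, sigma, width, f)
    er = repulsion_forces(x, pairs, npairs, sigma, 1.0, rcut, f)
    return eb, ea, ed, ec, er


@njit(cache=True, fastmath=True, error_model="numpy")
def integrate(
    x0, v0, n_steps, dt, gamma, temp, mass, seed, stride,
    bidx, br0, kb, aidx, at0, ka, didx, dp0c, dp0s, kd1, kd3,
    cidx, cr0, ceps, sigma, width,
    excl_keys, eps_rep, rcut, skin,
    k_umb, q_center, q_lam, q_beta_w,
    frames, epot_out, ebias_out, ekin_out,
):
    """BAOAB Langevin (gamma > 0) / velocity Verlet (gamma == 0).

    Frames, potential energies (bias excluded), bias energies and kinetic
    energies are written at every ``stride`` steps. Returns the index of
    the first non-finite step, or -1 on success.
    """
    n = x0.shape[0]
    x = x0.copy()
    v = v0.copy()
    f = np.zeros((n, 3))
    # splitmix64-seeded xorshift128+ state for the thermostat noise
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for k in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[k] = w ^ (w >> np.uint64(31))
    gp = np.empty(2)
    s_buf = np.empty(cidx.shape[0])
    max_pairs = n * 96
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    rlist = rcut + skin
    npairs = build_pairs(x, n, rlist, excl_keys, pairs)
    x_ref = x.copy()

    c1 = math.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = math.sqrt((1.0 - c1 * c1) * temp / mass) if gamma > 0.0 else 0.0
    hdtm = 0.5 * dt / mass

    eb, ea, ed, ec, er = compute_forces(
        x, f, bidx, br0, kb, aidx, at0, ka, didx, dp0c, dp0s, kd1, kd3,
        cidx, cr0, ceps, sigma, width, pairs, npairs, eps_rep, rcut,
    )
    ebias = 0.0
    if k_umb > 0.0:
        ebias, _ = smooth_q_forces(x, cidx, cr0, q_lam, q_beta_w, k_umb,
                                   q_center, f, s_buf)

    frame_idx = 0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            v[i, 0] += hdtm * f[i, 0]
            v[i, 1] += hdtm * f[i, 1]
            v[i, 2] += hdtm * f[i, 2]
        # A: half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        # O: thermostat
        if gamma > 0.0:
            for i in range(n):
                _gauss_pair(state, gp)
                v[i, 0] = c1 * v[i, 0] + c2 * gp[0]
                v[i, 1] = c1 * v[i, 1] + c2 * gp[1]
                _gauss_pair(state, gp)
                v[i, 2] = c1 * v[i, 2] + c2 * gp[0]
        # A: half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]

        # neighbor-list refresh when any particle moved > skin/2
        maxd2 = 0.0
        for i in range(n):
            dx = x[i, 0] - x_ref[i, 0]
            dy = x[i, 1] - x_ref[i, 1]
            dz = x[i, 2] - x_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > 0.25 * skin * skin:
            npairs = build_pairs(x, n, rlist, excl_keys, pairs)
            for i in range(n):
                x_ref[i, 0] = x[i, 0]
                x_ref[i, 1] = x[i, 1]
                x_ref[i, 2] = x[i, 2]

        eb, ea, ed, ec, er = compute_forces(
            x, f, bidx, br0, kb, aidx, at0, ka, didx, dp0c, dp0s, kd1, kd3,
            cidx, cr0, ceps, sigma, width, pairs, npairs, eps_rep, rcut,
        )
        ebias = 0.0
        if k_umb > 0.0:
            ebias, _ = smooth_q_forces(x, cidx, cr0, q_lam, q_beta_w, k_umb,
                                       q_center, f, s_buf)
        # B: half kick
        for i in range(n):
            v[i, 0] += hdtm * f[i, 0]
            v[i, 1] += hdtm * f[i, 1]
            v[i, 2] += hdtm * f[i, 2]

        if (step + 1) % stride == 0:
            epot = eb + ea + ed + ec + er
            if not math.isfinite(epot):
                return step
            ekin = 0.0
            for i in range(n):
                ekin += v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            ekin *= 0.5 * mass
            if frame_idx < frames.shape[0]:
                for i in range(n):
                    frames[frame_idx, i, 0] = x[i, 0]
                    frames[frame_idx, i, 1] = x[i, 1]
                    frames[frame_idx, i, 2] = x[i, 2]
                epot_out[frame_idx] = epot
                ebias_out[frame_idx] = ebias
                ekin_out[frame_idx] = ekin
                frame_idx += 1

    # copy the final state back so callers can continue runs
    for i in range(n):
        x0[i, 0] = x[i, 0]
        x0[i, 1] = x[i, 1]
        x0[i, 2] = x[i, 2]
        v0[i, 0] = v[i, 0]
        v0[i, 1] = v[i, 1]
        v0[i, 2] = v[i, 2]
    return -1
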