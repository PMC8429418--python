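"""Numba-compiled core of the voxel Monte Carlo photon transport.

Single-threaded for bit-reproducibility; the public API lives in
:mod:`spinepdt.transport`.  Random numbers come from an inline xorshift128+
generator (seeded via splitmix64), and scatter azimuths are drawn by
unit-circle rejection to avoid trig calls - both standard speed tricks in
photon-packet codes.

Weight ledger convention: ``tallies[0]`` absorbed weight, ``tallies[1]``
escaped weight, ``tallies[2]`` net weight created by Russian roulette
(survivor gains minus kill losses), so that
``absorbed + escaped - roulette_net == launched`` to float precision.
"""

import numpy as np
from numba import njit

__all__ = ["hg_cos_theta", "fresnel_unpolarized", "trace_batch"]

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _seed_state(seed):
    """Expand a 31-bit seed into xorshift128+ state via splitmix64."""
    st = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        st[i] = x ^ (x >> np.uint64(31))
    return st


@njit(cache=True, inline="always")
def _rand(st):
    """Uniform double in [0, 1) from xorshift128+ state ``st`` (mutated)."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    st[1] = s1
    return np.float64((s1 + s0) >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _rand_azimuth(st):
    """(cos psi, sin psi) uniform on the circle, by rejection from the square."""
    while True:
        a = 2.0 * _rand(st) - 1.0
        b = 2.0 * _rand(st) - 1.0
        r2 = a * a + b * b
        if 1e-12 < r2 <= 1.0:
            inv = 1.0 / r2
            return (a * a - b * b) * inv, 2.0 * a * b * inv


@njit(cache=True, fastmath=True)
def hg_cos_theta(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine."""
    if g > 1e-6 or g < -1e-6:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        return ct
    return 2.0 * u - 1.0


@njit(cache=True, fastmath=True)
def fresnel_unpolarized(n1, n2, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ``ci``; 1 beyond
    the critical angle."""
    if n1 == n2:
        return 0.0
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def trace_batch(labels, sx, sy, sz, ox, oy, oz,
                mu_a, mu_s, gg, nn,
                pos, dirs, seed, w_roulette, p_survive,
                fluence, tallies):
    """Trace one batch of photon packets through the labelled voxel grid.

    Scoring is the track-length estimator: each traversed path segment adds
    ``weight * length`` to its voxel (normalisation to fluence per unit
    energy happens in the caller).  Fresnel reflection/refraction is applied
    at axis-aligned voxel faces where the refractive index changes; packets
    transmitted into label 0 (air) or off the grid are tallied as escaped.
    """
    st = _seed_state(seed)
    nx, ny, nz = labels.shape
    npk = pos.shape[0]
    inv_p_survive = 1.0 / p_survive
    for ip in range(npk):
        x = pos[ip, 0]
        y = pos[ip, 1]
        z = pos[ip, 2]
        ux = dirs[ip, 0]
        uy = dirs[ip, 1]
        uz = dirs[ip, 2]
        ix = int(np.floor((x - ox) / sx))
        iy = int(np.floor((y - oy) / sy))
        iz = int(np.floor((z - oz) / sz))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz \
                or labels[ix, iy, iz] == 0:
            tallies[1] += 1.0
            continue
        w = 1.0
        tau = -np.log(1.0 - _rand(st))
        while True:
            lbl = labels[ix, iy, iz]
            mt = mu_a[lbl] + mu_s[lbl]
            # distances to the voxel faces along the current direction
            if ux > 0.0:
                dbx = ((ix + 1) * sx + ox - x) / ux
            elif ux < 0.0:
                dbx = (ix * sx + ox - x) / ux
            else:
                dbx = 1e30
            if uy > 0.0:
                dby = ((iy + 1) * sy + oy - y) / uy
            elif uy < 0.0:
                dby = (iy * sy + oy - y) / uy
            else:
                dby = 1e30
            if uz > 0.0:
                dbz = ((iz + 1) * sz + oz - z) / uz
            elif uz < 0.0:
                dbz = (iz * sz + oz - z) / uz
            else:
                dbz = 1e30
            axis = 0
            dmin = dbx
            if dby < dmin:
                dmin = dby
                axis = 1
            if dbz < dmin:
                dmin = dbz
                axis = 2
            if dmin < 0.0:
                dmin = 0.0
            s_int = tau / mt
            if s_int <= dmin:
                # interaction inside the current voxel
                fluence[ix, iy, iz] += w * s_int
                x += ux * s_int
                y += uy * s_int
                z += uz * s_int
                aw = w * mu_a[lbl] / mt
                tallies[0] += aw
                w -= aw
                if w < w_roulette:
                    if _rand(st) < p_survive:
                        nw = w * inv_p_survive
                        tallies[2] += nw - w
                        w = nw
                    else:
                        tallies[2] -= w
                        break
                ct = hg_cos_theta(gg[lbl], _rand(st))
                stheta = np.sqrt(1.0 - ct * ct)
                cp, sp = _rand_azimuth(st)
                if uz > 0.99999 or uz < -0.99999:
                    ux = stheta * cp
                    uy = stheta * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    tx = stheta * (ux * uz * cp - uy * sp) / den + ux * ct
                    ty = stheta * (uy * uz * cp + ux * sp) / den + uy * ct
                    tz = -stheta * cp * den + uz * ct
                    inv = 1.0 / np.sqrt(tx * tx + ty * ty + tz * tz)
                    ux = tx * inv
                    uy = ty * inv
                    uz = tz * inv
                tau = -np.log(1.0 - _rand(st))
            else:
                # advance to the voxel face
                fluence[ix, iy, iz] += w * dmin
                tau -= mt * dmin
                x += ux * dmin
                y += uy * dmin
                z += uz * dmin
                jx = ix
                jy = iy
                jz = iz
                if axis == 0:
                    if ux > 0.0:
                        jx = ix + 1
                        x = (ix + 1) * sx + ox
                    else:
                        jx = ix - 1
                        x = ix * sx + ox
                elif axis == 1:
                    if uy > 0.0:
                        jy = iy + 1
                        y = (iy + 1) * sy + oy
                    else:
                        jy = iy - 1
                        y = iy * sy + oy
                else:
                    if uz > 0.0:
                        jz = iz + 1
                        z = (iz + 1) * sz + oz
                    else:
                        jz = iz - 1
                        z = iz * sz + oz
                off_grid = jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
                if off_grid:
                    nlbl = 0
                else:
                    nlbl = labels[jx, jy, jz]
                n1 = nn[lbl]
                n2 = nn[nlbl]
                if n1 != n2:
                    if axis == 0:
                        ci = ux if ux > 0.0 else -ux
                    elif axis == 1:
                        ci = uy if uy > 0.0 else -uy
                    else:
                        ci = uz if uz > 0.0 else -uz
                    refl = fresnel_unpolarized(n1, n2, ci)
                    if _rand(st) < refl:
                        # specular reflection about the face normal; stay put
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                        continue
                    # refraction by Snell's law at the axis-aligned face
                    ratio = n1 / n2
                    st2 = ratio * ratio * (1.0 - ci * ci)
                    ct2 = np.sqrt(1.0 - st2) if st2 < 1.0 else 0.0
                    if axis == 0:
                        sgn = 1.0 if ux > 0.0 else -1.0
                        uy *= ratio
                        uz *= ratio
                        ux = sgn * ct2
                    elif axis == 1:
                        sgn = 1.0 if uy > 0.0 else -1.0
                        ux *= ratio
                        uz *= ratio
                        uy = sgn * ct2
                    else:
                        sgn = 1.0 if uz > 0.0 else -1.0
                        ux *= ratio
                        uy *= ratio
                        uz = sgn * ct2
                    inv = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux *= inv
                    uy *= inv
                    uz *= inv
                if off_grid or nlbl == 0:
                    tallies[1] += w
                    break
                ix = jx
                iy = jy
                iz = jz
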