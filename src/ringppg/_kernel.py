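"""Compiled weighted-photon transport kernel.

All geometry is axis-parallel (finger axis = z), so every boundary is either
a circle in the cross-sectional plane or one of the two absorbing end caps;
ray/boundary intersection reduces to a 2-D quadratic plus two plane tests.

The per-photon RNG is a splitmix64 stream keyed on (run seed, photon index),
giving counter-style reproducibility: results are bit-identical for a fixed
seed regardless of how photons would be batched.
"""

import math

import numpy as np
from numba import njit

# SimulationResult tally slots
T_LAUNCHED = 0
T_ABSORBED = 1
T_ESCAPED = 2
T_DETECTED = 3
T_DET_MICRO = 4
T_DET_ARTERY = 5
T_DET_COUNT = 6
T_DET_MICRO_COUNT = 7
T_CAPPED = 8
N_TALLIES = 9

FLAG_MICRO = 1
FLAG_ARTERY = 2

_EPS = 1e-7  # mm nudge off boundaries
_BIG = 1e30


@njit(cache=True, inline="always")
def _splitmix64(state):
    state = np.uint64(state + np.uint64(0x9E3779B97F4A7C15))
    z = state
    z = np.uint64((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9))
    z = np.uint64((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB))
    z = np.uint64(z ^ (z >> np.uint64(31)))
    return state, z


@njit(cache=True, inline="always")
def _uniform(state):
    """Uniform draw in (0, 1]."""
    state, z = _splitmix64(state)
    return state, ((z >> np.uint64(11)) + np.uint64(1)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - t * t) / (2.0 * g)


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, cos_t, phi):
    """Rotate direction by polar angle acos(cos_t), azimuth phi (MCML spin)."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cphi
        ny = sin_t * sphi
        nz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cphi - uy * sphi) / den + ux * cos_t
        ny = sin_t * (uy * uz * cphi + ux * sphi) / den + uy * cos_t
        nz = -sin_t * cphi * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _circle_hit(x, y, ux, uy, cx, cy, radius):
    """Smallest path length t > _EPS to the circle |p + t·u2 − c| = radius.

    t is measured in 3-D path length; (ux, uy) is the 2-D projection of the
    unit direction (|u2| ≤ 1), handled by the quadratic's 'a' coefficient.
    """
    a = ux * ux + uy * uy
    if a < 1e-18:
        return _BIG
    dx = x - cx
    dy = y - cy
    b = 2.0 * (dx * ux + dy * uy)
    c = dx * dx + dy * dy - radius * radius
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    if t1 > _EPS:
        return t1
    if t2 > _EPS:
        return t2
    return _BIG


@njit(cache=True, inline="always")
def _locate(x, y, n_emb, emb_cx, emb_cy, emb_r, emb_region,
            n_ann, ann_router, ann_region, outer_radius):
    """Region index at (x, y); -1 = ambient. Embedded cylinders shadow annuli."""
    for i in range(n_emb):
        dx = x - emb_cx[i]
        dy = y - emb_cy[i]
        if dx * dx + dy * dy < emb_r[i] * emb_r[i]:
            return emb_region[i]
    r = math.sqrt(x * x + y * y)
    if r >= outer_radius:
        return -1
    for i in range(n_ann):
        if r < ann_router[i]:
            return ann_region[i]
    return ann_region[n_ann - 1]


@njit(cache=True, inline="always")
def _fresnel_R(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance; cos_i ≥ 0. Returns (R, cos_t)."""
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    eta = n1 / n2
    sin_t2 = eta * eta * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True)
def transport_kernel(
    n_photons,
    seed,
    # geometry: embedded cylinders then annuli (inner->outer)
    emb_cx, emb_cy, emb_r, emb_region,
    ann_router, ann_region,
    outer_radius, axial_length,
    # per-region optics at the run wavelength
    mu_a, mu_s, g_arr, n_arr, flag_arr,
    n_ambient,
    # source / detector patches (radians, mm)
    led_phi, led_half_ap, pd_phi, pd_half_ap, patch_half_z,
    collimated,
    pd_cos_min,  # acceptance-angle cut on exit cos (<= -1 disables)
    # transport constants
    roulette_threshold, roulette_survival, max_steps,
):
    n_emb = emb_cx.shape[0]
    n_ann = ann_router.shape[0]
    tallies = np.zeros(N_TALLIES, dtype=np.float64)
    z_mid = 0.5 * axial_length

    for ip in range(n_photons):
        state = np.uint64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                          + np.uint64(ip) * np.uint64(0xD1B54A32D192ED03))
        # warm up the stream so nearby (seed, ip) keys decorrelate
        state, _ = _uniform(state)

        state, u = _uniform(state)
        phi0 = led_phi + (2.0 * u - 1.0) * led_half_ap
        state, u = _uniform(state)
        z = z_mid + (2.0 * u - 1.0) * patch_half_z
        r0 = outer_radius - _EPS
        x = r0 * math.cos(phi0)
        y = r0 * math.sin(phi0)
        # inward surface normal
        inx = -math.cos(phi0)
        iny = -math.sin(phi0)
        if collimated:
            ux, uy, uz = inx, iny, 0.0
        else:
            state, u1 = _uniform(state)
            state, u2 = _uniform(state)
            cos_l = math.sqrt(u1)  # Lambertian about the inward normal
            sin_l = math.sqrt(max(0.0, 1.0 - u1))
            psi = 2.0 * math.pi * u2
            # tangent frame: t1 along circumference, t2 along the axis
            t1x = -math.sin(phi0)
            t1y = math.cos(phi0)
            ux = cos_l * inx + sin_l * math.cos(psi) * t1x
            uy = cos_l * iny + sin_l * math.cos(psi) * t1y
            uz = sin_l * math.sin(psi)

        w = 1.0
        flags = 0
        tallies[T_LAUNCHED] += 1.0
        steps = 0
        alive = True

        while alive:
            steps += 1
            if steps > max_steps:
                tallies[T_ABSORBED] += w
                tallies[T_CAPPED] += 1.0
                break
            region = _locate(x, y, n_emb, emb_cx, emb_cy, emb_r, emb_region,
                             n_ann, ann_router, ann_region, outer_radius)
            if region < 0:
                # numerically stranded outside: count as escaped
                tallies[T_ESCAPED] += w
                break
            flags |= flag_arr[region]
            mua = mu_a[region]
            mus = mu_s[region]
            mut = mua + mus
            if mut > 0.0:
                state, u = _uniform(state)
                s = -math.log(u) / mut
            else:
                s = _BIG

            # nearest boundary along the direction of flight
            db = _BIG
            hit_kind = 0  # 1 = annulus circle, 2 = embedded circle, 3 = end cap
            hit_idx = -1
            for i in range(n_ann):
                t = _circle_hit(x, y, ux, uy, 0.0, 0.0, ann_router[i])
                if t < db:
                    db = t
                    hit_kind = 1
                    hit_idx = i
            for i in range(n_emb):
                t = _circle_hit(x, y, ux, uy, emb_cx[i], emb_cy[i], emb_r[i])
                if t < db:
                    db = t
                    hit_kind = 2
                    hit_idx = i
            if abs(uz) > 1e-18:
                t = (axial_length - z) / uz if uz > 0.0 else (0.0 - z) / uz
                if _EPS < t < db:
                    db = t
                    hit_kind = 3

            if s < db:
                # interior interaction: implicit capture + HG scatter
                x += ux * s
                y += uy * s
                z += uz * s
                tallies[T_ABSORBED] += w * (mua / mut)
                w *= mus / mut
                if w <= 0.0:
                    break
                state, u1 = _uniform(state)
                state, u2 = _uniform(state)
                cos_t = _hg_cos(g_arr[region], u1)
                ux, uy, uz = _spin(ux, uy, uz, cos_t, 2.0 * math.pi * u2)
                if w < roulette_threshold:
                    state, u = _uniform(state)
                    if u <= roulette_survival:
                        w_new = w / roulette_survival
                        tallies[T_ABSORBED] += w - w_new  # keeps the ledger exact
                        w = w_new
                    else:
                        tallies[T_ABSORBED] += w
                        break
                continue

            # move to the boundary
            x += ux * db
            y += uy * db
            z += uz * db
            if hit_kind == 3:
                tallies[T_ESCAPED] += w  # absorbing end caps
                break

            # surface normal of the crossed circle
            if hit_kind == 1:
                nrm = math.sqrt(x * x + y * y)
                nx = x / nrm
                ny = y / nrm
            else:
                dx = x - emb_cx[hit_idx]
                dy = y - emb_cy[hit_idx]
                nrm = math.sqrt(dx * dx + dy * dy)
                nx = dx / nrm
                ny = dy / nrm
            cos_i = ux * nx + uy * ny  # signed; >0 means leaving the circle
            sgn = 1.0 if cos_i >= 0.0 else -1.0
            # orient normal along travel so cos_i >= 0
            nx *= sgn
            ny *= sgn
            cos_i = abs(cos_i)

            n1 = n_arr[region]
            # medium on the far side, probed slightly beyond the surface
            x2 = x + ux * _EPS
            y2 = y + uy * _EPS
            next_region = _locate(x2, y2, n_emb, emb_cx, emb_cy, emb_r, emb_region,
                                  n_ann, ann_router, ann_region, outer_radius)
            n2 = n_ambient if next_region < 0 else n_arr[next_region]

            if n1 == n2:
                x, y = x2, y2
                if next_region < 0:
                    # crossed the outer surface into ambient
                    alive = False
                    _tally_exit(tallies, x, y, z, ux, uy, nx, ny, w, flags,
                                pd_phi, pd_half_ap, patch_half_z, z_mid, pd_cos_min)
                continue

            R, cos_refr = _fresnel_R(n1, n2, cos_i)
            state, u = _uniform(state)
            if u <= R:
                # specular reflection back into the current region
                dot = ux * nx + uy * ny
                ux -= 2.0 * dot * nx
                uy -= 2.0 * dot * ny
                x += ux * _EPS
                y += uy * _EPS
                continue
            # refraction (vector Snell with normal opposing incidence)
            eta = n1 / n2
            # incidence-side normal m = -n (so m·u = -cos_i)
            mx = -nx
            my = -ny
            tx = eta * ux + (eta * cos_i - cos_refr) * mx
            ty = eta * uy + (eta * cos_i - cos_refr) * my
            tz = eta * uz
            norm = math.sqrt(tx * tx + ty * ty + tz * tz)
            ux, uy, uz = tx / norm, ty / norm, tz / norm
            x += ux * _EPS
            y += uy * _EPS
            if next_region < 0:
                alive = False
                _tally_exit(tallies, x, y, z, ux, uy, nx, ny, w, flags,
                            pd_phi, pd_half_ap, patch_half_z, z_mid, pd_cos_min)

    return tallies


@njit(cache=True, inline="always")
def _tally_exit(tallies, x, y, z, ux, uy, nx, ny, w, flags,
                pd_phi, pd_half_ap, patch_half_z, z_mid, pd_cos_min):
    """Classify a photon that crossed the outer surface into ambient."""
    phi = math.atan2(y, x)
    d = phi - pd_phi
    while d > math.pi:
        d -= 2.0 * math.pi
    while d < -math.pi:
        d += 2.0 * math.pi
    in_patch = abs(d) <= pd_half_ap and abs(z - z_mid) <= patch_half_z
    if in_patch and pd_cos_min > -1.0:
        exit_cos = ux * nx + uy * ny
        if exit_cos < pd_cos_min:
            in_patch = False
    if in_patch:
        tallies[T_DETECTED] += w
        tallies[T_DET_COUNT] += 1.0
        if flags & FLAG_MICRO:
            tallies[T_DET_MICRO] += w
            tallies[T_DET_MICRO_COUNT] += 1.0
        if flags & FLAG_ARTERY:
            tallies[T_DET_ARTERY] += w
    else:
        tallies[T_ESCAPED] += w
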