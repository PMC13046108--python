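"""Compiled Monte Carlo transport kernel.

History-by-history voxel transport of megavoltage photons and electrons
through the layered phantom. Photons use Woodcock (delta) tracking with
photoelectric / Klein–Nishina Compton / pair-production channels;
electrons and positrons use class-II condensed history: restricted
collision stopping, Highland Gaussian multiple scattering, explicit
Møller knock-on (delta-ray) production above the regional threshold, and
continuous radiative loss (not rescored — bremsstrahlung photons leave
the thin slab). Positrons annihilate at rest into two 511 keV photons.

Randomness: a counter-based scheme — each history derives an independent
xorshift64* stream whose state is seeded with splitmix64(seed, history
index) — so runs are bit-reproducible and independent of execution order.

All lengths in mm within the geometry, cross sections in cm^-1 (the
kernel converts), energies in MeV.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_MASK = U64(0xFFFFFFFFFFFFFFFF)
MEC2 = 0.51099895
PHOTON_CUT = 0.01  # MeV, deposit locally below
GMAX_MOLLER = 2.3  # rejection envelope bound for the Moller factor
THETA_HARD = 0.25  # rad: elastic events beyond this angle sampled singly


# ---------------------------------------------------------------------------
# counter-based RNG: splitmix64 seeding + xorshift64* stream
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _seed_state(seed, idx):
    z = (U64(seed) + U64(idx) * U64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)) & _MASK
    z = z ^ (z >> U64(31))
    if z == U64(0):
        z = U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, inline="always")
def _rnd(state):
    s = state
    s ^= (s << U64(13)) & _MASK
    s ^= s >> U64(7)
    s ^= (s << U64(17)) & _MASK
    val = ((s * U64(0x2545F4914F6CDD1D)) & _MASK) >> U64(11)
    return (float(val) * (1.0 / 9007199254740992.0)), s


@njit(cache=True, inline="always")
def _gauss(state):
    u1, state = _rnd(state)
    u2, state = _rnd(state)
    if u1 < 1e-300:
        u1 = 1e-300
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2), state


# ---------------------------------------------------------------------------
# geometry / table lookups
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mat_at(x, y, z, zb, layer_mat, tattoo_idx, quad_ids, half_lat):
    if x < -half_lat or x > half_lat or y < -half_lat or y > half_lat:
        return -1
    if z < zb[0] or z >= zb[-1]:
        return -1
    lo = 0
    hi = len(zb) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if z >= zb[mid]:
            lo = mid
        else:
            hi = mid
    if lo == tattoo_idx:
        q = 0
        if x >= 0.0:
            q += 1
        if y < 0.0:
            q += 2
        return quad_ids[q]
    return layer_mat[lo]


@njit(cache=True, inline="always")
def _interp(table, mat, e, loge0, inv_dloge, ne):
    t = (np.log(e) - loge0) * inv_dloge
    if t < 0.0:
        t = 0.0
    if t > ne - 1.001:
        t = ne - 1.001
    k = int(t)
    f = t - k
    return table[mat, k] * (1.0 - f) + table[mat, k + 1] * f


@njit(cache=True, inline="always")
def _interp1(table, e, loge0, inv_dloge, ne):
    t = (np.log(e) - loge0) * inv_dloge
    if t < 0.0:
        t = 0.0
    if t > ne - 1.001:
        t = ne - 1.001
    k = int(t)
    f = t - k
    return table[k] * (1.0 - f) + table[k + 1] * f


@njit(cache=True, inline="always")
def _rotate(u, v, w, ct, phi):
    st = np.sqrt(max(1.0 - ct * ct, 0.0))
    cf = np.cos(phi)
    sf = np.sin(phi)
    sz = np.sqrt(max(1.0 - w * w, 0.0))
    if sz < 1e-10:
        un = st * cf
        vn = st * sf
        wn = ct if w > 0.0 else -ct
        if w < 0.0:
            vn = -vn
        return un, vn, wn
    un = u * ct + st * (u * w * cf - v * sf) / sz
    vn = v * ct + st * (v * w * cf + u * sf) / sz
    wn = w * ct - sz * st * cf
    n = np.sqrt(un * un + vn * vn + wn * wn)
    return un / n, vn / n, wn / n


# ---------------------------------------------------------------------------
# Compton (Klein–Nishina) sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_compton(e, state):
    """Sample scattered-photon fraction eps and cos(theta) from KN."""
    k = e / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        u1, state = _rnd(state)
        u2, state = _rnd(state)
        u3, state = _rnd(state)
        if u1 < a1 / (a1 + a2):
            eps = eps0 * np.exp(a1 * u2)
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * u2)
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if u3 <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            ct = 1.0 - t
            return eps, ct, state


@njit(cache=True)
def sample_compton_batch(e, n, seed):
    """n KN samples: returns (eps, cos_theta) arrays (statistics tests)."""
    out_eps = np.empty(n)
    out_ct = np.empty(n)
    for i in range(n):
        state = _seed_state(seed, i)
        eps, ct, state = _sample_compton(e, state)
        out_eps[i] = eps
        out_ct[i] = ct
    return out_eps, out_ct


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def simulate(
    n_hist,
    seed,
    nbatch,
    # beam
    ptype0,
    e0,
    esig,
    field_half,
    src_div,
    ssd_mm,
    # geometry
    zb,
    layer_mat,
    tattoo_idx,
    quad_ids,
    half_lat,
    tz0,
    tz1,
    z_kill_e,
    fine_z,
    # tables (linear attenuation cm^-1, stopping MeV/cm)
    loge0,
    inv_dloge,
    ne,
    mu_pe,
    mu_c,
    mu_pr,
    mu_tot,
    mu_maj,
    ld_out,
    ld_tat,
    srad,
    delta_out,
    delta_tat,
    rho,
    x0_g,
    spr,
    moller_cm,
    ruth_cm,
    ms_corr,
    # scoring
    sx0,
    dxy,
    nx,
    ny,
    dzs,
    nz,
    edep_m,
    edep_w,
    totals,
):
    max_stack = 512
    st_type = np.empty(max_stack, dtype=np.int64)  # 0 gamma, 1 e-, 2 e+
    st_e = np.empty(max_stack)
    st_x = np.empty(max_stack)
    st_y = np.empty(max_stack)
    st_z = np.empty(max_stack)
    st_u = np.empty(max_stack)
    st_v = np.empty(max_stack)
    st_w = np.empty(max_stack)

    zmax_score = dzs * nz

    for hist in range(n_hist):
        state = _seed_state(seed, hist)
        ib = (hist * nbatch) // n_hist

        # --- source ---
        g, state = _gauss(state)
        e_start = e0 + esig * g
        if e_start < 0.02:
            e_start = 0.02
        u1, state = _rnd(state)
        u2, state = _rnd(state)
        x = field_half * (2.0 * u1 - 1.0)
        y = field_half * (2.0 * u2 - 1.0)
        if src_div == 1:
            norm = np.sqrt(x * x + y * y + ssd_mm * ssd_mm)
            du, dv, dw = x / norm, y / norm, ssd_mm / norm
        else:
            du, dv, dw = 0.0, 0.0, 1.0
        totals[0] += e_start

        nstk = 1
        st_type[0] = ptype0
        st_e[0] = e_start
        st_x[0] = x
        st_y[0] = y
        st_z[0] = 0.0
        st_u[0] = du
        st_v[0] = dv
        st_w[0] = dw

        while nstk > 0:
            nstk -= 1
            ptype = st_type[nstk]
            e = st_e[nstk]
            x = st_x[nstk]
            y = st_y[nstk]
            z = st_z[nstk]
            u = st_u[nstk]
            v = st_v[nstk]
            w = st_w[nstk]

            if ptype == 0:
                # ---------------- photon (Woodcock tracking) ----------------
                while True:
                    if e < PHOTON_CUT:
                        mat = _mat_at(
                            x, y, z, zb, layer_mat, tattoo_idx, quad_ids, half_lat
                        )
                        if mat >= 0 and z < zmax_score:
                            ix = int((x - sx0) / dxy)
                            iy = int((y - sx0) / dxy)
                            iz = int(z / dzs)
                            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                                edep_m[ib, ix, iy, iz] += e
                                edep_w[ib, ix, iy, iz] += e * _interp(
                                    spr, mat, e, loge0, inv_dloge, ne
                                )
                        if mat >= 0:
                            totals[1] += e
                        break
                    mj = _interp1(mu_maj, e, loge0, inv_dloge, ne)
                    r, state = _rnd(state)
                    s_mm = -np.log(max(r, 1e-300)) / mj * 10.0
                    x += u * s_mm
                    y += v * s_mm
                    z += w * s_mm
                    mat = _mat_at(
                        x, y, z, zb, layer_mat, tattoo_idx, quad_ids, half_lat
                    )
                    if mat < 0:
                        break  # escaped
                    mt = _interp(mu_tot, mat, e, loge0, inv_dloge, ne)
                    r, state = _rnd(state)
                    if r * mj > mt:
                        continue  # virtual collision
                    # real interaction: pick channel
                    mpe = _interp(mu_pe, mat, e, loge0, inv_dloge, ne)
                    mc = _interp(mu_c, mat, e, loge0, inv_dloge, ne)
                    r, state = _rnd(state)
                    rm = r * mt
                    if rm < mpe:
                        # photoelectric: full absorption on one electron
                        if nstk < max_stack:
                            st_type[nstk] = 1
                            st_e[nstk] = e
                            st_x[nstk] = x
                            st_y[nstk] = y
                            st_z[nstk] = z
                            st_u[nstk] = u
                            st_v[nstk] = v
                            st_w[nstk] = w
                            nstk += 1
                        break
                    elif rm < mpe + mc:
                        # Compton scatter
                        eps, ct, state = _sample_compton(e, state)
                        phi, state = _rnd(state)
                        phi *= 2.0 * np.pi
                        t_e = e * (1.0 - eps)
                        # electron direction from momentum conservation
                        st = np.sqrt(max(1.0 - ct * ct, 0.0))
                        pe_x = 1.0 - eps * ct
                        pe_t = eps * st
                        pn = np.sqrt(pe_x * pe_x + pe_t * pe_t)
                        ct_e = pe_x / pn if pn > 0 else 1.0
                        if nstk < max_stack and t_e > 0.0:
                            eu, ev, ew = _rotate(u, v, w, ct_e, phi + np.pi)
                            st_type[nstk] = 1
                            st_e[nstk] = t_e
                            st_x[nstk] = x
                            st_y[nstk] = y
                            st_z[nstk] = z
                            st_u[nstk] = eu
                            st_v[nstk] = ev
                            st_w[nstk] = ew
                            nstk += 1
                        u, v, w = _rotate(u, v, w, ct, phi)
                        e *= eps
                        continue
                    else:
                        # pair production
                        avail = e - 2.0 * MEC2
                        if avail <= 0.0:
                            continue
                        r, state = _rnd(state)
                        t1 = avail * r
                        t2 = avail - t1
                        for ipair in range(2):
                            te = t1 if ipair == 0 else t2
                            # small characteristic emission angle ~ mc^2/E
                            g1, state = _gauss(state)
                            g2, state = _gauss(state)
                            sig = MEC2 / (te + MEC2)
                            cth = np.cos(np.sqrt(g1 * g1 + g2 * g2) * sig)
                            phi, state = _rnd(state)
                            if nstk < max_stack:
                                pu, pv, pw = _rotate(
                                    u, v, w, cth, 2.0 * np.pi * phi
                                )
                                st_type[nstk] = 1 if ipair == 0 else 2
                                st_e[nstk] = te
                                st_x[nstk] = x
                                st_y[nstk] = y
                                st_z[nstk] = z
                                st_u[nstk] = pu
                                st_v[nstk] = pv
                                st_w[nstk] = pw
                                nstk += 1
                        break

            else:
                # ---------------- electron / positron ----------------
                is_pos = ptype == 2
                alive = True
                while alive:
                    mat = _mat_at(
                        x, y, z, zb, layer_mat, tattoo_idx, quad_ids, half_lat
                    )
                    if mat < 0 or z >= z_kill_e:
                        alive = False
                        break
                    in_tat = tz0 <= z < tz1
                    dcut = delta_tat if in_tat else delta_out
                    if e <= dcut:
                        # below transport cutoff: deposit locally
                        if z < zmax_score:
                            ix = int((x - sx0) / dxy)
                            iy = int((y - sx0) / dxy)
                            iz = int(z / dzs)
                            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                                edep_m[ib, ix, iy, iz] += e
                                edep_w[ib, ix, iy, iz] += e * _interp(
                                    spr, mat, e, loge0, inv_dloge, ne
                                )
                        totals[1] += e
                        if is_pos:
                            # annihilation at rest: two 511 keV photons
                            r1, state = _rnd(state)
                            r2, state = _rnd(state)
                            aw = 2.0 * r1 - 1.0
                            ast = np.sqrt(max(1.0 - aw * aw, 0.0))
                            aphi = 2.0 * np.pi * r2
                            au = ast * np.cos(aphi)
                            av = ast * np.sin(aphi)
                            for sgn in (1.0, -1.0):
                                if nstk < max_stack:
                                    st_type[nstk] = 0
                                    st_e[nstk] = MEC2
                                    st_x[nstk] = x
                                    st_y[nstk] = y
                                    st_z[nstk] = z
                                    st_u[nstk] = sgn * au
                                    st_v[nstk] = sgn * av
                                    st_w[nstk] = sgn * aw
                                    nstk += 1
                        alive = False
                        break

                    ld = ld_tat if in_tat else ld_out
                    lcol = _interp(ld, mat, e, loge0, inv_dloge, ne)

                    # step limits: geometric cap, 5% energy loss, z-boundary
                    cap_mm = 0.02 if z < fine_z else 0.5
                    s_e_mm = 0.05 * e / lcol * 10.0
                    s_mm = cap_mm if cap_mm < s_e_mm else s_e_mm
                    # exact split at the next z-layer boundary
                    lo = 0
                    hi = len(zb) - 1
                    while hi - lo > 1:
                        mid = (lo + hi) // 2
                        if z >= zb[mid]:
                            lo = mid
                        else:
                            hi = mid
                    if w > 1e-9:
                        s_b = (zb[hi] - z) / w + 1e-4
                        if s_b < s_mm:
                            s_mm = s_b
                    elif w < -1e-9:
                        s_b = (zb[lo] - z) / w + 1e-4
                        if s_b < s_mm:
                            s_mm = s_b
                    if s_mm < 1e-5:
                        s_mm = 1e-5
                    s_cm = s_mm * 0.1

                    emid = e - 0.5 * lcol * s_cm
                    if emid < 0.6 * dcut:
                        emid = 0.6 * dcut
                    lcol = _interp(ld, mat, emid, loge0, inv_dloge, ne)
                    de_col = lcol * s_cm
                    de_rad = _interp(srad, mat, emid, loge0, inv_dloge, ne) * s_cm
                    if de_col + de_rad > e:
                        de_col = e
                        de_rad = 0.0

                    # Moller knock-on production above the regional threshold
                    t_delta = 0.0
                    eta = dcut / emid if emid > 0 else 1.0
                    if eta < 0.5:
                        tau = emid / MEC2
                        gam = tau + 1.0
                        beta2 = 1.0 - 1.0 / (gam * gam)
                        cand_rate = (
                            moller_cm[mat]
                            / (beta2 * emid)
                            * GMAX_MOLLER
                            * (1.0 / eta - 2.0)
                        )
                        pd = cand_rate * s_cm
                        r, state = _rnd(state)
                        if r < pd:
                            r2, state = _rnd(state)
                            epsd = eta / (1.0 - r2 * (1.0 - 2.0 * eta))
                            # full Moller factor for rejection
                            c1 = (tau / (tau + 1.0)) ** 2
                            c2 = (2.0 * tau + 1.0) / ((tau + 1.0) ** 2)
                            f = (
                                1.0 / (epsd * epsd)
                                + 1.0 / ((1.0 - epsd) * (1.0 - epsd))
                                + c1
                                - c2 / (epsd * (1.0 - epsd))
                            )
                            r3, state = _rnd(state)
                            if r3 < f * epsd * epsd / GMAX_MOLLER:
                                t_delta = epsd * emid
                                if t_delta > e - de_col:
                                    t_delta = 0.0
                        if t_delta > 0.0 and nstk < max_stack:
                            # knock-on direction from free-electron kinematics
                            ctd = np.sqrt(
                                t_delta
                                * (emid + 2.0 * MEC2)
                                / (emid * (t_delta + 2.0 * MEC2))
                            )
                            if ctd > 1.0:
                                ctd = 1.0
                            r4, state = _rnd(state)
                            duu, dvv, dww = _rotate(
                                u, v, w, ctd, 2.0 * np.pi * r4
                            )
                            st_type[nstk] = 1
                            st_e[nstk] = t_delta
                            st_x[nstk] = x
                            st_y[nstk] = y
                            st_z[nstk] = z
                            st_u[nstk] = duu
                            st_v[nstk] = dvv
                            st_w[nstk] = dww
                            nstk += 1

                    # score the continuous deposit at the step midpoint
                    xm = x + 0.5 * s_mm * u
                    ym = y + 0.5 * s_mm * v
                    zm = z + 0.5 * s_mm * w
                    if 0.0 <= zm < zmax_score:
                        ix = int((xm - sx0) / dxy)
                        iy = int((ym - sx0) / dxy)
                        iz = int(zm / dzs)
                        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                            edep_m[ib, ix, iy, iz] += de_col
                            edep_w[ib, ix, iy, iz] += de_col * _interp(
                                spr, mat, emid, loge0, inv_dloge, ne
                            )
                    totals[1] += de_col

                    # advance, then deflect (Highland Gaussian)
                    x += u * s_mm
                    y += v * s_mm
                    z += w * s_mm
                    ds_g = s_cm * rho[mat]
                    xr = ds_g / x0_g[mat]
                    tau = emid / MEC2
                    pbeta = emid * (tau + 2.0) / (tau + 1.0)
                    # Lynch–Dahl: the log correction uses the aggregate
                    # (CSDA-scale) path, not the substep, so that summed
                    # substep variances reproduce the full-thickness width
                    corr = _interp(ms_corr, mat, emid, loge0, inv_dloge, ne)
                    th0 = 13.6 / pbeta * np.sqrt(xr) * corr
                    r5, state = _rnd(state)
                    th = th0 * np.sqrt(-2.0 * np.log(max(r5, 1e-300)))
                    if th > 1.5:
                        th = 1.5
                    r6, state = _rnd(state)
                    u, v, w = _rotate(u, v, w, np.cos(th), 2.0 * np.pi * r6)

                    # hard elastic tail (screened Rutherford + Mott factor):
                    # single large-angle nuclear deflections beyond the
                    # Gaussian condensed-history width
                    tc = np.sin(0.5 * THETA_HARD) ** 2
                    hr = (
                        ruth_cm[mat]
                        * (MEC2 / (2.0 * pbeta)) ** 2
                        * (1.0 / tc - 1.0)
                    )
                    rh, state = _rnd(state)
                    if rh < hr * s_cm:
                        gam = emid / MEC2 + 1.0
                        beta2 = 1.0 - 1.0 / (gam * gam)
                        for _attempt in range(8):
                            r7, state = _rnd(state)
                            tt = tc / (1.0 - r7 * (1.0 - tc))
                            r8, state = _rnd(state)
                            if r8 < 1.0 - beta2 * tt:  # Mott spin factor
                                r9, state = _rnd(state)
                                u, v, w = _rotate(
                                    u, v, w, 1.0 - 2.0 * tt, 2.0 * np.pi * r9
                                )
                                break

                    e = e - de_col - de_rad - t_delta
                    if e < 1e-6:
                        e = 1e-6

    return 0
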