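"""Numba kernel for the analog photon/electron history loop.

The kernel works on packed per-material tables sampled on a uniform
log-energy grid (1 keV - 2 MeV): photon partial attenuation (cm^2/g),
photoelectric fluorescer fractions for Bi and Zn, and electron stopping
powers (MeV cm^2/g).  Geometry is a 1-D stack of slabs; directions are
tracked in full 3-D but boundaries exist only in z.  Secondaries are
managed on a LIFO stack; transport is strictly analog, so every keV of the
primary energy ends in a layer tally or an escape account and conservation
is exact to float round-off.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_PHOTON = 0
KIND_ELECTRON = 1

_STACK_MAX = 2048
_DIR_EPS = 1e-12


@njit(cache=True, inline="always")
def _lookup_exp(row, ln_e, ln_e0, inv_dln, ng):
    """exp of linear interpolation of a ln-valued row on the uniform log grid."""
    t = (ln_e - ln_e0) * inv_dln
    if t <= 0.0:
        return math.exp(row[0])
    if t >= ng - 1:
        return math.exp(row[ng - 1])
    i = int(t)
    f = t - i
    return math.exp(row[i] * (1.0 - f) + row[i + 1] * f)


@njit(cache=True, inline="always")
def _lookup_lin(row, ln_e, ln_e0, inv_dln, ng):
    t = (ln_e - ln_e0) * inv_dln
    if t <= 0.0:
        return row[0]
    if t >= ng - 1:
        return row[ng - 1]
    i = int(t)
    f = t - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(cache=True, inline="always")
def _rotate(u, v, w, cost, phi):
    """Rotate a unit vector by polar angle (cos given) and azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    if s < 1e-10:
        sign = 1.0 if w >= 0.0 else -1.0
        nu = sint * cosp
        nv = sint * sinp
        nw = sign * cost
    else:
        nu = u * cost + sint * (u * w * cosp - v * sinp) / s
        nv = v * cost + sint * (v * w * cosp + u * sinp) / s
        nw = w * cost - s * sint * cosp
    norm = math.sqrt(nu * nu + nv * nv + nw * nw)
    return nu / norm, nv / norm, nw / norm


@njit(cache=True, inline="always")
def _sample_sauter_cos(e_kev, rng):
    """Photoelectron polar angle wrt the photon: Sauter-Gavrila K-shell
    distribution, pdf ~ (1 - c^2) / (1 - beta c)^4."""
    gamma = 1.0 + e_kev / 510.99895
    beta = math.sqrt(max(0.0, 1.0 - 1.0 / (gamma * gamma)))
    if beta < 1e-6:
        return 2.0 * rng.random() - 1.0
    c_star = (-1.0 + math.sqrt(1.0 + 8.0 * beta * beta)) / (2.0 * beta)
    g_max = (1.0 - c_star * c_star) / (1.0 - beta * c_star) ** 4
    while True:
        c = 2.0 * rng.random() - 1.0
        g = (1.0 - c * c) / (1.0 - beta * c) ** 4
        if rng.random() * g_max <= g:
            return c


@njit(cache=True, inline="always")
def _sample_compton_eps(alpha, rng):
    """Klein-Nishina epsilon = E'/E via composition-rejection sampling."""
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -math.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = math.exp(-a1 * rng.random())
        else:
            eps = math.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * rng.random())
        t = (1.0 - eps) / (alpha * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps, 1.0 - t


@njit(cache=True)
def run_batch(
    n_hist,
    kind0,
    e0_kev,
    zb,                 # layer boundaries, cm, length n_layers+1
    mat_of_layer,       # material index per layer
    rho,                # per material, g/cm^3
    ln_mu_pe, ln_mu_in, ln_mu_coh,   # [mat, grid] ln(cm^2/g)
    p_bi, p_zn,                      # [mat, grid] PE fluorescer fractions
    ln_s_col, ln_s_rad,              # [mat, grid] ln(MeV cm^2/g)
    inv_x0,                          # per material, cm^2/g
    ln_e0_grid, inv_dln, ng,
    edge_bi, omega_bi, ekx_bi,
    edge_zn, omega_zn, ekx_zn,
    photon_cutoff_kev, electron_cutoff_kev,
    coherent_on, absorb_only, brems_on,
    mu_scale,
    max_step_frac,
    rng,
    out_sum, out_sumsq,              # length n_layers+2 (escape up, down)
):
    n_layers = len(zb) - 1
    iup = n_layers          # escape-upstream tally slot
    idn = n_layers + 1      # escape-downstream tally slot
    me2 = 510.99895 * 2.0

    st_kind = np.empty(_STACK_MAX, dtype=np.int8)
    st_e = np.empty(_STACK_MAX, dtype=np.float64)
    st_z = np.empty(_STACK_MAX, dtype=np.float64)
    st_u = np.empty(_STACK_MAX, dtype=np.float64)
    st_v = np.empty(_STACK_MAX, dtype=np.float64)
    st_w = np.empty(_STACK_MAX, dtype=np.float64)
    st_l = np.empty(_STACK_MAX, dtype=np.int64)

    dep = np.empty(n_layers + 2, dtype=np.float64)

    for _h in range(n_hist):
        for i in range(n_layers + 2):
            dep[i] = 0.0
        nstk = 1
        st_kind[0] = kind0
        st_e[0] = e0_kev
        st_z[0] = zb[0]
        st_u[0] = 0.0
        st_v[0] = 0.0
        st_w[0] = 1.0
        st_l[0] = 0

        while nstk > 0:
            nstk -= 1
            kind = st_kind[nstk]
            e = st_e[nstk]
            z = st_z[nstk]
            u = st_u[nstk]
            v = st_v[nstk]
            w = st_w[nstk]
            lay = st_l[nstk]

            if kind == KIND_PHOTON:
                # ---------------- photon ----------------
                while True:
                    if e < photon_cutoff_kev:
                        dep[lay] += e
                        break
                    m = mat_of_layer[lay]
                    ln_e = math.log(e)
                    mpe = _lookup_exp(ln_mu_pe[m], ln_e, ln_e0_grid, inv_dln, ng)
                    min_ = _lookup_exp(ln_mu_in[m], ln_e, ln_e0_grid, inv_dln, ng)
                    if coherent_on:
                        mco = _lookup_exp(ln_mu_coh[m], ln_e, ln_e0_grid, inv_dln, ng)
                    else:
                        mco = 0.0
                    mu_tot = (mpe + min_ + mco) * rho[m] * mu_scale
                    s = -math.log(1.0 - rng.random()) / mu_tot
                    if w > _DIR_EPS:
                        t_b = (zb[lay + 1] - z) / w
                        next_l = lay + 1
                    elif w < -_DIR_EPS:
                        t_b = (zb[lay] - z) / w
                        next_l = lay - 1
                    else:
                        t_b = 1e300
                        next_l = lay
                    if s >= t_b:
                        # cross into the next layer; exponential is memoryless
                        if next_l < 0:
                            dep[iup] += e
                            break
                        if next_l >= n_layers:
                            dep[idn] += e
                            break
                        z = zb[lay + 1] if next_l > lay else zb[lay]
                        lay = next_l
                        continue
                    z += s * w
                    if absorb_only:
                        dep[lay] += e
                        break
                    x = rng.random() * (mpe + min_ + mco)
                    if x < mpe:
                        # photoelectric
                        r_el = rng.random()
                        pb = _lookup_lin(p_bi[m], ln_e, ln_e0_grid, inv_dln, ng)
                        pz = _lookup_lin(p_zn[m], ln_e, ln_e0_grid, inv_dln, ng)
                        e_electron = e
                        if r_el < pb and e > edge_bi:
                            if rng.random() < omega_bi:
                                e_electron = e - edge_bi
                                dep[lay] += edge_bi - ekx_bi
                                if nstk < _STACK_MAX - 1:
                                    cf = 2.0 * rng.random() - 1.0
                                    sf = math.sqrt(max(0.0, 1.0 - cf * cf))
                                    ph = 2.0 * math.pi * rng.random()
                                    st_kind[nstk] = KIND_PHOTON
                                    st_e[nstk] = ekx_bi
                                    st_z[nstk] = z
                                    st_u[nstk] = sf * math.cos(ph)
                                    st_v[nstk] = sf * math.sin(ph)
                                    st_w[nstk] = cf
                                    st_l[nstk] = lay
                                    nstk += 1
                                else:
                                    dep[lay] += ekx_bi
                        elif r_el < pb + pz and e > edge_zn:
                            if rng.random() < omega_zn:
                                e_electron = e - edge_zn
                                dep[lay] += edge_zn - ekx_zn
                                if nstk < _STACK_MAX - 1:
                                    cf = 2.0 * rng.random() - 1.0
                                    sf = math.sqrt(max(0.0, 1.0 - cf * cf))
                                    ph = 2.0 * math.pi * rng.random()
                                    st_kind[nstk] = KIND_PHOTON
                                    st_e[nstk] = ekx_zn
                                    st_z[nstk] = z
                                    st_u[nstk] = sf * math.cos(ph)
                                    st_v[nstk] = sf * math.sin(ph)
                                    st_w[nstk] = cf
                                    st_l[nstk] = lay
                                    nstk += 1
                                else:
                                    dep[lay] += ekx_zn
                        # photoelectron: Sauter-Gavrila angle about the photon
                        if nstk < _STACK_MAX - 1:
                            ce = _sample_sauter_cos(e_electron, rng)
                            eu, ev, ew = _rotate(
                                u, v, w, ce, 2.0 * math.pi * rng.random()
                            )
                            st_kind[nstk] = KIND_ELECTRON
                            st_e[nstk] = e_electron
                            st_z[nstk] = z
                            st_u[nstk] = eu
                            st_v[nstk] = ev
                            st_w[nstk] = ew
                            st_l[nstk] = lay
                            nstk += 1
                        else:
                            dep[lay] += e_electron
                        break
                    elif x < mpe + min_:
                        # Compton on a free electron
                        alpha = e / 510.99895
                        eps, cost = _sample_compton_eps(alpha, rng)
                        e_sc = eps * e
                        e_el = e - e_sc
                        phi = 2.0 * math.pi * rng.random()
                        p_el = math.sqrt(e_el * (e_el + me2))
                        if p_el > 0.0:
                            cos_el = (e - e_sc * cost) / p_el
                            if cos_el > 1.0:
                                cos_el = 1.0
                            elif cos_el < -1.0:
                                cos_el = -1.0
                        else:
                            cos_el = 1.0
                        if nstk < _STACK_MAX - 1 and e_el > 0.0:
                            eu, ev, ew = _rotate(u, v, w, cos_el, phi + math.pi)
                            st_kind[nstk] = KIND_ELECTRON
                            st_e[nstk] = e_el
                            st_z[nstk] = z
                            st_u[nstk] = eu
                            st_v[nstk] = ev
                            st_w[nstk] = ew
                            st_l[nstk] = lay
                            nstk += 1
                        else:
                            dep[lay] += e_el
                        u, v, w = _rotate(u, v, w, cost, phi)
                        e = e_sc
                        continue
                    else:
                        # coherent: redirect, no energy transfer
                        while True:
                            c = 2.0 * rng.random() - 1.0
                            if rng.random() <= 0.5 * (1.0 + c * c):
                                break
                        u, v, w = _rotate(u, v, w, c, 2.0 * math.pi * rng.random())
                        continue
            else:
                # ---------------- electron ----------------
                while True:
                    if e <= electron_cutoff_kev:
                        dep[lay] += e
                        break
                    m = mat_of_layer[lay]
                    ln_e = math.log(e)
                    sc = _lookup_exp(ln_s_col[m], ln_e, ln_e0_grid, inv_dln, ng)
                    sr = _lookup_exp(ln_s_rad[m], ln_e, ln_e0_grid, inv_dln, ng)
                    stot_cm = (sc + sr) * rho[m]          # MeV/cm
                    thick = zb[lay + 1] - zb[lay]
                    ds = max_step_frac * (e / 1000.0) / stot_cm
                    if ds > 0.2 * thick:
                        ds = 0.2 * thick
                    if w > _DIR_EPS:
                        t_b = (zb[lay + 1] - z) / w
                        next_l = lay + 1
                    elif w < -_DIR_EPS:
                        t_b = (zb[lay] - z) / w
                        next_l = lay - 1
                    else:
                        t_b = 1e300
                        next_l = lay
                    crossing = t_b <= ds
                    if crossing:
                        ds = t_b
                    de_col = sc * rho[m] * ds * 1000.0    # keV
                    if de_col > e:
                        de_col = e
                    dep[lay] += de_col
                    e_after = e - de_col
                    if brems_on and e_after > photon_cutoff_kev:
                        p_brem = sr * rho[m] * ds * 1000.0 / e
                        if rng.random() < p_brem:
                            k = photon_cutoff_kev * (
                                e_after / photon_cutoff_kev
                            ) ** rng.random()
                            e_after -= k
                            if nstk < _STACK_MAX - 1:
                                st_kind[nstk] = KIND_PHOTON
                                st_e[nstk] = k
                                st_z[nstk] = z
                                st_u[nstk] = u
                                st_v[nstk] = v
                                st_w[nstk] = w
                                st_l[nstk] = lay
                                nstk += 1
                            else:
                                dep[lay] += k
                    # move along the pre-deflection direction, then deflect
                    z += ds * w
                    x_gcm2 = rho[m] * ds
                    if x_gcm2 > 0.0:
                        pc = math.sqrt(e * (e + me2)) / 1000.0
                        beta = pc * 1000.0 / (e + 510.99895)
                        ratio = x_gcm2 * inv_x0[m]
                        corr = 1.0 + 0.038 * math.log(ratio)
                        if corr < 0.25:
                            corr = 0.25
                        sig = 13.6 / (beta * pc) * math.sqrt(ratio) * corr
                        theta = sig * math.sqrt(-2.0 * math.log(1.0 - rng.random()))
                        if theta > 0.0:
                            u, v, w = _rotate(
                                u, v, w, math.cos(theta), 2.0 * math.pi * rng.random()
                            )
                    if crossing:
                        if next_l < 0:
                            dep[iup] += e_after
                            e_after = 0.0
                            break
                        if next_l >= n_layers:
                            dep[idn] += e_after
                            e_after = 0.0
                            break
                        z = zb[lay + 1] if next_l > lay else zb[lay]
                        lay = next_l
                    e = e_after
                # end electron loop

        for i in range(n_layers + 2):
            d = dep[i] / 1000.0      # MeV
            out_sum[i] += d
            out_sumsq[i] += d * d
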