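"""Compiled inner loop: implicit branched-cable integration.

One backward-Euler step of the voltage equation on the Hines-ordered tree,
staggered with Rush-Larsen gating updates and explicit calcium/ion-pool
updates.  Voltage-dependent steady states and per-step decay factors
exp(-dt/tau) are pre-tabulated on a fine voltage grid (and a log10[Ca] grid
for the SK gate), so the hot loop is table interpolation plus a symmetric
tree solve.

Units inside the kernel: mV, ms, nA, uS, nF, mA/cm^2 for current densities.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# mM per (mA/cm^2 * 1/cm * ms): 1e-6 C/(ms cm^2) / F * 1e6 mM/(mol/cm^3)
FLUX_COEF = 1e-6 / 96_485.0 * 1e6
ECA_COEF_MV = 3.08e5 * 8.314 / (2.0 * 96_485.0)
RT_F_MV = 1e3 * 8.314 * 308.0 / 96_485.0


@njit(cache=True, inline="always")
def _interp(table, x, x0, inv_dx):
    u = (x - x0) * inv_dx
    if u < 0.0:
        u = 0.0
    hi = table.shape[0] - 1.000001
    if u > hi:
        u = hi
    i = int(u)
    f = u - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True)
def integrate(
    nsteps, dt, t0,
    # state (mutated in place)
    v, m, h, ng, lg, mq, mca, q, ca, nai, nao, ki, ko, ena, ek,
    # topology / passive
    parent, gax, gax_tot, cdt, gleak_abs, eleak,
    # absolute conductances (uS) and mechanism index lists
    gna_abs, gkdr_abs, gkcnq_abs, gca_abs, gsk_abs,
    na_idx, kdr_idx, kcnq_idx, ca_idx, sk_idx,
    area_cm2,
    # voltage tables
    v0t, inv_dv,
    minf_t, mexp_t, hinf_t, hexp_t,
    ninf_t, nexp_t, linf_t, lexp_t,
    mqinf_t, mqexp_t, mcainf_t, mcaexp_t,
    # SK tables over log10(ca)
    l0t, inv_dl, qinf_t, qexp_t,
    ca_rest,
    # ion dynamics / pump
    ion_on, pump_on, ipmax, km_pump, sov_i, sov_o, jna0, jk0,
    # stimuli (expanded pulses)
    stim_comp, stim_amp, stim_t0, stim_t1,
    # recording
    rec_idx, rec_stride, out_v, out_ca, out_ena, out_ek,
):
    n = v.shape[0]
    gt = np.empty(n)
    gb = np.empty(n)
    d = np.empty(n)
    b = np.empty(n)
    ica = np.zeros(n)

    # record initial state
    for s in range(rec_idx.shape[0]):
        c = rec_idx[s]
        out_v[0, s] = v[c]
        out_ca[0, s] = ca[c]
        out_ena[0, s] = ena[c]
        out_ek[0, s] = ek[c]

    for step in range(nsteps):
        t = t0 + step * dt

        # --- gating updates (Rush-Larsen, using pre-step V) ---
        for k in range(na_idx.shape[0]):
            i = na_idx[k]
            vi = v[i]
            m[i] = _interp(minf_t, vi, v0t, inv_dv) + (
                m[i] - _interp(minf_t, vi, v0t, inv_dv)
            ) * _interp(mexp_t, vi, v0t, inv_dv)
            h[i] = _interp(hinf_t, vi, v0t, inv_dv) + (
                h[i] - _interp(hinf_t, vi, v0t, inv_dv)
            ) * _interp(hexp_t, vi, v0t, inv_dv)
        for k in range(kdr_idx.shape[0]):
            i = kdr_idx[k]
            vi = v[i]
            ng[i] = _interp(ninf_t, vi, v0t, inv_dv) + (
                ng[i] - _interp(ninf_t, vi, v0t, inv_dv)
            ) * _interp(nexp_t, vi, v0t, inv_dv)
            lg[i] = _interp(linf_t, vi, v0t, inv_dv) + (
                lg[i] - _interp(linf_t, vi, v0t, inv_dv)
            ) * _interp(lexp_t, vi, v0t, inv_dv)
        for k in range(kcnq_idx.shape[0]):
            i = kcnq_idx[k]
            vi = v[i]
            mq[i] = _interp(mqinf_t, vi, v0t, inv_dv) + (
                mq[i] - _interp(mqinf_t, vi, v0t, inv_dv)
            ) * _interp(mqexp_t, vi, v0t, inv_dv)
        for k in range(ca_idx.shape[0]):
            i = ca_idx[k]
            vi = v[i]
            mca[i] = _interp(mcainf_t, vi, v0t, inv_dv) + (
                mca[i] - _interp(mcainf_t, vi, v0t, inv_dv)
            ) * _interp(mcaexp_t, vi, v0t, inv_dv)
        for k in range(sk_idx.shape[0]):
            i = sk_idx[k]
            lc = np.log10(ca[i])
            q[i] = _interp(qinf_t, lc, l0t, inv_dl) + (
                q[i] - _interp(qinf_t, lc, l0t, inv_dl)
            ) * _interp(qexp_t, lc, l0t, inv_dl)

        # --- assemble linearized membrane currents ---
        for i in range(n):
            gt[i] = gleak_abs[i]
            gb[i] = gleak_abs[i] * eleak[i]
        for k in range(na_idx.shape[0]):
            i = na_idx[k]
            g = gna_abs[i] * m[i] * m[i] * m[i] * h[i]
            gt[i] += g
            gb[i] += g * ena[i]
        for k in range(kdr_idx.shape[0]):
            i = kdr_idx[k]
            g = gkdr_abs[i] * ng[i] * ng[i] * ng[i] * lg[i]
            gt[i] += g
            gb[i] += g * ek[i]
        for k in range(kcnq_idx.shape[0]):
            i = kcnq_idx[k]
            g = gkcnq_abs[i] * mq[i]
            gt[i] += g
            gb[i] += g * ek[i]
        for k in range(ca_idx.shape[0]):
            i = ca_idx[k]
            eca = ECA_COEF_MV * np.log(2.0 / ca[i])
            g = gca_abs[i] * mca[i] * mca[i]
            gt[i] += g
            gb[i] += g * eca
        for k in range(sk_idx.shape[0]):
            i = sk_idx[k]
            g = gsk_abs[i] * q[i] * q[i]
            gt[i] += g
            gb[i] += g * ek[i]
        if pump_on:
            for i in range(n):
                if ipmax[i] > 0.0 and area_cm2[i] > 0.0:
                    ip = ipmax[i] * nai[i] / (nai[i] + km_pump)  # mA/cm^2 net outward
                    gb[i] -= ip * area_cm2[i] * 1e6  # nA

        # --- stimulus currents ---
        for s in range(stim_comp.shape[0]):
            if stim_t0[s] <= t < stim_t1[s]:
                gb[stim_comp[s]] += stim_amp[s]

        # --- backward-Euler tree solve ---
        for i in range(n):
            d[i] = cdt[i] + gt[i] + gax_tot[i]
            b[i] = cdt[i] * v[i] + gb[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / d[i]
            d[p] -= f * gax[i]
            b[p] += f * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + gax[i] * v[parent[i]]) / d[i]

        # --- calcium dynamics (explicit, post-solve V) ---
        for k in range(ca_idx.shape[0]):
            i = ca_idx[k]
            eca = ECA_COEF_MV * np.log(2.0 / ca[i])
            ica[i] = gca_abs[i] * mca[i] * mca[i] * (v[i] - eca) / (
                area_cm2[i] * 1e6
            )  # mA/cm^2
            ca[i] += dt * (-0.026 * ica[i] - (ca[i] - ca_rest) / 20.0)
            if ca[i] < 1e-12:
                ca[i] = 1e-12

        # --- Na+/K+ pools and Nernst potentials ---
        if ion_on:
            for i in range(n):
                if area_cm2[i] <= 0.0:
                    continue
                inv_a = 1.0 / (area_cm2[i] * 1e6)
                ina = gna_abs[i] * m[i] * m[i] * m[i] * h[i] * (v[i] - ena[i]) * inv_a
                ik = (
                    gkdr_abs[i] * ng[i] * ng[i] * ng[i] * lg[i]
                    + gkcnq_abs[i] * mq[i]
                    + gsk_abs[i] * q[i] * q[i]
                ) * (v[i] - ek[i]) * inv_a
                if pump_on and ipmax[i] > 0.0:
                    ip = ipmax[i] * nai[i] / (nai[i] + km_pump)
                    ina += 3.0 * ip
                    ik -= 2.0 * ip
                jna = (ina - jna0[i]) * FLUX_COEF
                jk = (ik - jk0[i]) * FLUX_COEF
                nai[i] -= jna * sov_i[i] * dt
                nao[i] += jna * sov_o[i] * dt
                ki[i] -= jk * sov_i[i] * dt
                ko[i] += jk * sov_o[i] * dt
                if nai[i] < 1e-6:
                    nai[i] = 1e-6
                if ki[i] < 1e-6:
                    ki[i] = 1e-6
                if nao[i] < 1e-6:
                    nao[i] = 1e-6
                if ko[i] < 1e-6:
                    ko[i] = 1e-6
                ena[i] = RT_F_MV * np.log(nao[i] / nai[i])
                ek[i] = RT_F_MV * np.log(ko[i] / ki[i])

        # --- recording ---
        if (step + 1) % rec_stride == 0:
            r = (step + 1) // rec_stride
            if r < out_v.shape[0]:
                for s in range(rec_idx.shape[0]):
                    c = rec_idx[s]
                    out_v[r, s] = v[c]
                    out_ca[r, s] = ca[c]
                    out_ena[r, s] = ena[c]
                    out_ek[r, s] = ek[c]

    return 0
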