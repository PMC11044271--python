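"""Numba kernels for the toy engine's inner loops.

These mirror the reference numpy path in :mod:`swishx.engine` (non-periodic
systems only) and are cross-checked against it in the test suite.  The
BAOAB loop consumes a pre-generated Gaussian noise block so that all
randomness flows through numpy Generators seeded by the orchestrator.

Error codes returned by the run kernel:
    0   success
    1   hard-core overlap between a particle pair
    2   potential energy blow-up (non-finite or |U| beyond bound)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

HARD_CORE_FRACTION = 0.35
ENERGY_BLOWUP_BOUND = 1.0e10

# role ids, kept in sync with swishx.engine
_SOLVENT = 0
_SOLUTE_APOLAR = 1


@njit(cache=True)
def energy_forces_nb(
    pos,
    roles,
    eps,
    sig,
    rc,
    shift,
    lam,
    frozen,
    # per-coordinate tethers
    tether_k,
    tether_ref,
    # gate double well on x of one particle (gate_idx < 0 disables)
    gate_idx,
    gate_B,
    gate_xmid,
    gate_half,
    gate_wallk,
    gate_slo,
    gate_shi,
    # spherical confinement on mobile particles (conf_k <= 0 disables)
    conf_k,
    conf_R,
    # contact-map upper wall (len(wall_i) == 0 disables)
    wall_i,
    wall_j,
    wall_r0,
    wall_n,
    wall_m,
    wall_wmax,
    wall_kappa,
    # interprobe repulsion over probe indices (rep_k <= 0 disables)
    probe_idx,
    rep_d,
    rep_k,
    forces,
):
    """Fill ``forces`` with -grad U and return the energy decomposition.

    Returns (u_ww, u_ws, u_ss, u_restraint, u_external, cv, err_pair).
    ``err_pair`` is -1 on success, otherwise i*N+j of an overlapping pair.
    Pairs with both particles frozen are skipped (their constant energy is
    added back by the caller).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    u_ww = 0.0
    u_ws = 0.0
    u_ss = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if frozen[i] and frozen[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            ri = roles[i]
            rj = roles[j]
            s = sig[ri, rj]
            floor = HARD_CORE_FRACTION * s
            if r2 < floor * floor:
                return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, i * n + j)
            c = rc[ri, rj]
            if r2 >= c * c:
                continue
            e = eps[ri, rj]
            sr6 = (s * s / r2) ** 3
            u = 4.0 * e * (sr6 * sr6 - sr6) - shift[ri, rj]
            dudr_over_r = -24.0 * e * (2.0 * sr6 * sr6 - sr6) / r2
            scale = 1.0
            if (ri == _SOLVENT and rj == _SOLVENT):
                u_ww += u
            elif (ri == _SOLVENT and rj == _SOLUTE_APOLAR) or (
                ri == _SOLUTE_APOLAR and rj == _SOLVENT
            ):
                u_ws += u
                scale = lam
            else:
                u_ss += u
            f = -scale * dudr_over_r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz

    u_ext = 0.0
    for i in range(n):
        for d in range(3):
            k = tether_k[i, d]
            if k > 0.0:
                dd = pos[i, d] - tether_ref[i, d]
                u_ext += 0.5 * k * dd * dd
                forces[i, d] -= k * dd

    if gate_idx >= 0:
        sg = (pos[gate_idx, 0] - gate_xmid) / gate_half
        u_ext += gate_B * (sg * sg - 1.0) ** 2
        forces[gate_idx, 0] += -4.0 * gate_B * sg * (sg * sg - 1.0) / gate_half
        if sg < gate_slo:
            dd = (sg - gate_slo) * gate_half
            u_ext += 0.5 * gate_wallk * dd * dd
            forces[gate_idx, 0] += -gate_wallk * dd
        elif sg > gate_shi:
            dd = (sg - gate_shi) * gate_half
            u_ext += 0.5 * gate_wallk * dd * dd
            forces[gate_idx, 0] += -gate_wallk * dd

    if conf_k > 0.0:
        for i in range(n):
            if frozen[i]:
                continue
            r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r > conf_R and r > 1e-12:
                over = r - conf_R
                u_ext += 0.5 * conf_k * over * over
                fmag = -conf_k * over / r
                forces[i, 0] += fmag * pos[i, 0]
                forces[i, 1] += fmag * pos[i, 1]
                forces[i, 2] += fmag * pos[i, 2]

    u_restr = 0.0
    cv = 0.0
    nw = wall_i.shape[0]
    if nw > 0:
        # rational switch S(r) = (1-(r/r0)^n)/(1-(r/r0)^m)
        svals = np.empty(nw)
        rvals = np.empty(nw)
        for p in range(nw):
            a = wall_i[p]
            b = wall_j[p]
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            x = r / wall_r0
            if abs(x - 1.0) < 1e-9:
                sv = (wall_n / wall_m) * (1.0 + 0.5 * (wall_n - wall_m) * (x - 1.0))
            else:
                sv = (1.0 - x**wall_n) / (1.0 - x**wall_m)
            svals[p] = sv
            rvals[p] = r
            cv += sv
        if cv > wall_wmax and wall_kappa > 0.0:
            u_restr += 0.5 * wall_kappa * (cv - wall_wmax) ** 2
            dEdcv = wall_kappa * (cv - wall_wmax)
            for p in range(nw):
                a = wall_i[p]
                b = wall_j[p]
                r = rvals[p]
                if r < 1e-12:
                    continue
                x = r / wall_r0
                if abs(x - 1.0) < 1e-6:
                    dSdx = wall_n * (wall_n - wall_m) / (2.0 * wall_m)
                else:
                    den = 1.0 - x**wall_m
                    dSdx = (
                        -wall_n * x ** (wall_n - 1) * den
                        + wall_m * x ** (wall_m - 1) * (1.0 - x**wall_n)
                    ) / (den * den)
                dSdr = dSdx / wall_r0
                fmag = -dEdcv * dSdr / r
                dx = pos[a, 0] - pos[b, 0]
                dy = pos[a, 1] - pos[b, 1]
                dz = pos[a, 2] - pos[b, 2]
                forces[a, 0] += fmag * dx
                forces[a, 1] += fmag * dy
                forces[a, 2] += fmag * dz
                forces[b, 0] -= fmag * dx
                forces[b, 1] -= fmag * dy
                forces[b, 2] -= fmag * dz

    npr = probe_idx.shape[0]
    if rep_k > 0.0 and npr > 1:
        for a in range(npr):
            for b in range(a + 1, npr):
                ia = probe_idx[a]
                ib = probe_idx[b]
                dx = pos[ia, 0] - pos[ib, 0]
                dy = pos[ia, 1] - pos[ib, 1]
                dz = pos[ia, 2] - pos[ib, 2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r < rep_d and r > 1e-12:
                    u_restr += rep_k * (rep_d - r) ** 2
                    fmag = 2.0 * rep_k * (rep_d - r) / r
                    forces[ia, 0] += fmag * dx
                    forces[ia, 1] += fmag * dy
                    forces[ia, 2] += fmag * dz
                    forces[ib, 0] -= fmag * dx
                    forces[ib, 1] -= fmag * dy
                    forces[ib, 2] -= fmag * dz

    return (u_ww, u_ws, u_ss, u_restr, u_ext, cv, -1)


@njit(cache=True)
def bias_and_factor(u_total, beta, beta_j, bj_deltaF):
    """OPES MultiThermal bias V(U) and dV/dU via log-sum-exp.

    a_j = -(beta_j - beta) * U + beta_j * deltaF_j
    V   = -(1/beta) * (logsumexp(a) - log N_T)
    dV/dU = sum_j p_j * (beta_j - beta) / beta ,  p = softmax(a)
    """
    nt = beta_j.shape[0]
    amax = -1.0e300
    for j in range(nt):
        a = -(beta_j[j] - beta) * u_total + bj_deltaF[j]
        if a > amax:
            amax = a
    ssum = 0.0
    fsum = 0.0
    for j in range(nt):
        a = -(beta_j[j] - beta) * u_total + bj_deltaF[j]
        w = math.exp(a - amax)
        ssum += w
        fsum += w * (beta_j[j] - beta)
    v = -(amax + math.log(ssum / nt)) / beta
    factor = fsum / (ssum * beta)
    return v, factor


@njit(cache=True)
def baoab_run(
    pos,
    vel,
    masses,
    frozen,
    roles,
    eps,
    sig,
    rc,
    shift,
    lam,
    u_frozen_const,
    tether_k,
    tether_ref,
    gate_idx,
    gate_B,
    gate_xmid,
    gate_half,
    gate_wallk,
    gate_slo,
    gate_shi,
    conf_k,
    conf_R,
    wall_i,
    wall_j,
    wall_r0,
    wall_n,
    wall_m,
    wall_wmax,
    wall_kappa,
    probe_idx,
    rep_d,
    rep_k,
    bias_on,
    beta,
    beta_j,
    bj_deltaF,
    dt,
    gamma,
    temperature,
    noise,
    u_out,
    v_out,
    cv_out,
    gx_out,
):
    """Integrate ``n_steps = noise.shape[0]`` BAOAB steps in place.

    Records the physical potential U, bias V, wall CV and gate x coordinate
    for every step.  Returns (err_code, err_pair).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    forces = np.zeros((n, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))

    res = energy_forces_nb(
        pos, roles, eps, sig, rc, shift, lam, frozen,
        tether_k, tether_ref,
        gate_idx, gate_B, gate_xmid, gate_half, gate_wallk, gate_slo, gate_shi,
        conf_k, conf_R,
        wall_i, wall_j, wall_r0, wall_n, wall_m, wall_wmax, wall_kappa,
        probe_idx, rep_d, rep_k,
        forces,
    )
    if res[6] >= 0:
        return (1, res[6])
    u_phys = res[0] + lam * res[1] + res[2] + res[3] + res[4] + u_frozen_const
    if bias_on:
        v_bias, factor = bias_and_factor(u_phys, beta, beta_j, bj_deltaF)
        fscale = 1.0 + factor
    else:
        v_bias = 0.0
        fscale = 1.0
    for i in range(n):
        if frozen[i]:
            continue
        for d in range(3):
            forces[i, d] *= fscale

    for step in range(n_steps):
        for i in range(n):
            if frozen[i]:
                continue
            im = 1.0 / masses[i]
            svel = math.sqrt(temperature * im)
            for d in range(3):
                v = vel[i, d] + 0.5 * dt * forces[i, d] * im
                x = pos[i, d] + 0.5 * dt * v
                v = c1 * v + c2 * svel * noise[step, i, d]
                x = x + 0.5 * dt * v
                vel[i, d] = v
                pos[i, d] = x
        res = energy_forces_nb(
            pos, roles, eps, sig, rc, shift, lam, frozen,
            tether_k, tether_ref,
            gate_idx, gate_B, gate_xmid, gate_half, gate_wallk, gate_slo, gate_shi,
            conf_k, conf_R,
            wall_i, wall_j, wall_r0, wall_n, wall_m, wall_wmax, wall_kappa,
            probe_idx, rep_d, rep_k,
            forces,
        )
        if res[6] >= 0:
            return (1, res[6])
        u_phys = res[0] + lam * res[1] + res[2] + res[3] + res[4] + u_frozen_const
        if not math.isfinite(u_phys) or abs(u_phys) > ENERGY_BLOWUP_BOUND:
            return (2, -1)
        if bias_on:
            v_bias, factor = bias_and_factor(u_phys, beta, beta_j, bj_deltaF)
            fscale = 1.0 + factor
        else:
            v_bias = 0.0
            fscale = 1.0
        for i in range(n):
            if frozen[i]:
                continue
            for d in range(3):
                forces[i, d] *= fscale
        for i in range(n):
            if frozen[i]:
                continue
            im = 1.0 / masses[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] * im
        u_out[step] = u_phys
        v_out[step] = v_bias
        cv_out[step] = res[5]
        gx_out[step] = pos[gate_idx, 0] if gate_idx >= 0 else 0.0
    return (0, -1)


@njit(cache=True)
def baoab_harmonic_opes(
    x0,
    v0,
    k_spring,
    dt,
    gamma,
    temperature,
    bias_on,
    beta,
    beta_j,
    bj_deltaF,
    noise,
    u_out,
    v_out,
):
    """1-D harmonic well BAOAB with an OPES MultiThermal bias on U = k x^2 / 2.

    Used as the analytic calibration system for the bias estimator.  Records
    U and V every step; returns the final (x, v).
    """
    n_steps = noise.shape[0]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    svel = math.sqrt(temperature)
    x = x0
    v = v0
    u = 0.5 * k_spring * x * x
    if bias_on:
        vb, factor = bias_and_factor(u, beta, beta_j, bj_deltaF)
        fscale = 1.0 + factor
    else:
        vb = 0.0
        fscale = 1.0
    f = -k_spring * x * fscale
    for step in range(n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * svel * noise[step]
        x += 0.5 * dt * v
        u = 0.5 * k_spring * x * x
        if bias_on:
            vb, factor = bias_and_factor(u, beta, beta_j, bj_deltaF)
            fscale = 1.0 + factor
        else:
            vb = 0.0
            fscale = 1.0
        f = -k_spring * x * fscale
        v += 0.5 * dt * f
        u_out[step] = u
        v_out[step] = vb
    return x, v
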