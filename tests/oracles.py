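"""Independent oracles for the ODE model tests.

Everything here is coded separately from the package implementation: the
right-hand side is a per-process flux ledger (one explicit entry per
biological process, summed per compartment at the end), and the
integrator is a plain fixed-step classical RK4.  Both are deliberately
structured differently from the production code so that shared bugs are
unlikely.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# compartment order: N_S, N_P, N_R, N_D, P, B, V, I, M, C
NS, NP_, NR, ND, P_, B_, V_, I_, M_, C_ = range(10)


def ledger_rhs(variant, params, y):
    """Flux-ledger right-hand side: build the list of process fluxes,
    then add each flux to its source/sink compartments."""
    p = params
    has_R = variant.prey_types in ("N2", "N3", "N4")
    has_P = variant.prey_types in ("N3", "N4")
    has_D = variant.prey_types == "N4"
    dy = np.zeros(10)

    g = p.mu_max * y[M_] / (p.K_M + y[M_]) if (p.K_M + y[M_]) > 0 else 0.0

    de_novo = has_R and variant.resistance_origin in ("de_novo", "both")
    m = p.m if de_novo else 0.0

    # (i) growth of each prey phenotype, consuming medium one-for-one.
    # N_S divisions: fraction m mutates into N_R.
    flux = g * y[NS]
    dy[M_] -= flux
    dy[NS] += (1 - m) * flux
    if has_R:
        dy[NR] += m * flux
    if has_R:
        flux = g * y[NR]
        dy[M_] -= flux
        dy[NR] += flux
    if has_P:
        flux = g * y[NP_]
        dy[M_] -= flux
        m_p = m if has_D else 0.0
        # growth-coupled back conversion: N_P offspring are born N_S
        target = NS if variant.conversion in ("IG", "SG") else NP_
        dy[target] += (1 - m_p) * flux
        if has_D:
            dy[ND] += m_p * flux
    if has_D:
        flux = g * y[ND]
        dy[M_] -= flux
        dy[ND] += flux

    # (ii) Bdellovibrio attack on N_S and N_R -> bdelloplast
    susceptible = y[NS] + (y[NR] if has_R else 0.0)
    for idx, present in ((NS, True), (NR, has_R)):
        if not present:
            continue
        if variant.p_saturation == "Pii":
            flux = p.a_P * y[P_] * y[idx] / (p.K_P + susceptible) \
                if (p.K_P + susceptible) > 0 else 0.0
        else:
            flux = p.a_P * y[P_] * y[idx]
        dy[idx] -= flux
        dy[P_] -= flux
        dy[B_] += flux
        if variant.uses_signal and variant.signal_source in ("B_only", "both"):
            dy[C_] += p.sigma_C * flux

    # (iii) phage attack on N_S and N_P -> infected cell
    host = y[NS] + (y[NP_] if has_P else 0.0)
    for idx, present in ((NS, True), (NP_, has_P)):
        if not present:
            continue
        if variant.v_saturation == "Vii":
            flux = p.a_V * y[V_] * y[idx] / (p.K_V + host) \
                if (p.K_V + host) > 0 else 0.0
        else:
            flux = p.a_V * y[V_] * y[idx]
        dy[idx] -= flux
        dy[V_] -= flux
        dy[I_] += flux
        if variant.uses_signal and variant.signal_source in ("V_only", "both"):
            dy[C_] += p.sigma_C * flux

    # (iv+vi) bdelloplast resolution: progeny + nutrient release
    flux = p.k_B * y[B_]
    dy[B_] -= flux
    dy[P_] += p.beta_P * flux
    dy[M_] += p.eps_B * flux

    # (v+vii) infected-cell lysis: virions + nutrient release
    flux = p.k_I * y[I_]
    dy[I_] -= flux
    dy[V_] += p.beta_V * flux
    dy[M_] += p.eps_I * flux

    # (viii) Bdellovibrio mortality
    dy[P_] -= p.d_P * y[P_]

    # phenotype conversion N_S <-> N_P
    if has_P:
        if variant.conversion in ("S", "SG"):
            flux = p.k_sig * y[C_] * y[NS]
        else:
            flux = p.r_I * y[NS]
        dy[NS] -= flux
        dy[NP_] += flux
        if variant.conversion in ("I", "S"):
            flux = p.r_back * y[NP_]
            dy[NP_] -= flux
            dy[NS] += flux
    return dy


@njit(cache=True)
def _rk4_core(flags, th, y0, t_grid, h):
    """Classical fixed-step RK4 on a compact re-coding of the RHS."""
    n = y0.size
    out = np.zeros((t_grid.size, n))
    y = y0.copy()
    out[0] = y
    for gi in range(1, t_grid.size):
        t0, t1 = t_grid[gi - 1], t_grid[gi]
        nstep = max(1, int(np.ceil((t1 - t0) / h)))
        hh = (t1 - t0) / nstep
        for _ in range(nstep):
            k1 = _oracle_rhs(flags, th, y)
            k2 = _oracle_rhs(flags, th, y + 0.5 * hh * k1)
            k3 = _oracle_rhs(flags, th, y + 0.5 * hh * k2)
            k4 = _oracle_rhs(flags, th, y + hh * k3)
            y = y + (hh / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            for i in range(n):
                if y[i] < 0.0:
                    y[i] = 0.0
        out[gi] = y
    return out


@njit(cache=True)
def _oracle_rhs(flags, th, y):
    """Independent RHS coding used by the RK4 oracle (vector algebra
    rather than scalar accumulation)."""
    (mu_max, K_M, a_P, K_P, a_V, K_V, k_B, beta_P, k_I, beta_V,
     eps_B, eps_I, d_P, sigma_C, k_sig, r_I, r_back, m) = (
        th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
        th[9], th[10], th[11], th[12], th[13], th[14], th[15], th[16], th[17])
    lvl = flags[0]
    has_R = 1.0 if lvl >= 2 else 0.0
    has_P = 1.0 if lvl >= 3 else 0.0
    has_D = 1.0 if lvl >= 4 else 0.0
    sig_fwd = 1.0 if flags[1] == 1 else 0.0
    back_growth = 1.0 if flags[2] == 1 else 0.0
    de_novo = 1.0 if flags[6] == 1 else 0.0

    dy = np.zeros(10)
    g = mu_max * y[8] / (K_M + y[8]) if (K_M + y[8]) > 0 else 0.0
    mm = m * de_novo * has_R
    mp = m * de_novo * has_D

    grow = np.array([g * y[0], has_P * g * y[1], has_R * g * y[2],
                     has_D * g * y[3]])
    dy[8] -= grow[0] + grow[1] + grow[2] + grow[3]
    dy[0] += (1 - mm) * grow[0]
    dy[2] += mm * grow[0] + grow[2]
    dy[3] += grow[3] + mp * grow[1]
    dy[0] += back_growth * (1 - mp) * grow[1]
    dy[1] += (1 - back_growth) * (1 - mp) * grow[1]

    S = y[0] + has_R * y[2]
    if flags[7] == 1:
        fp = a_P * y[4] / (K_P + S) if (K_P + S) > 0 else 0.0
    else:
        fp = a_P * y[4]
    attP = np.array([fp * y[0], has_R * fp * y[2]])
    dy[0] -= attP[0]
    dy[2] -= attP[1]
    dy[4] -= attP[0] + attP[1]
    dy[5] += attP[0] + attP[1]

    H = y[0] + has_P * y[1]
    if flags[8] == 1:
        fv = a_V * y[6] / (K_V + H) if (K_V + H) > 0 else 0.0
    else:
        fv = a_V * y[6]
    attV = np.array([fv * y[0], has_P * fv * y[1]])
    dy[0] -= attV[0]
    dy[1] -= attV[1]
    dy[6] -= attV[0] + attV[1]
    dy[7] += attV[0] + attV[1]

    dy[5] -= k_B * y[5]
    dy[4] += beta_P * k_B * y[5] - d_P * y[4]
    dy[8] += eps_B * k_B * y[5] + eps_I * k_I * y[7]
    dy[7] -= k_I * y[7]
    dy[6] += beta_V * k_I * y[7]

    if has_P > 0:
        conv = sig_fwd * k_sig * y[9] * y[0] + (1 - sig_fwd) * r_I * y[0]
        dy[0] -= conv
        dy[1] += conv
        back = (1 - back_growth) * r_back * y[1]
        dy[1] -= back
        dy[0] += back
        if sig_fwd > 0:
            src = 0.0
            if flags[3] == 1:
                src += attP[0] + attP[1]
            if flags[4] == 1:
                src += attV[0] + attV[1]
            dy[9] += sigma_C * src
    return dy


def rk4_trajectory(variant, params, y0, t_grid, h=1e-3):
    """Fixed-step RK4 oracle trajectory on the requested grid."""
    return _rk4_core(
        variant.flags(), params.rhs_vector(),
        np.asarray(y0, dtype=float), np.asarray(t_grid, dtype=float), h,
    )
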