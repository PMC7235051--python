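"""Numba-compiled kernel for the joint-model log posterior and gradient.

This mirrors ``JointModel``'s pure-numpy implementation exactly (the test
suite asserts agreement to ~1e-10); it exists because NUTS needs hundreds of
thousands of gradient evaluations per fit and the numpy version is dispatch
-bound on these small arrays.  All branching flags are plain runtime booleans
so one compiled specialization serves every model variant.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    NUMBA_AVAILABLE = True
except Exception:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _digamma(x: float) -> float:
    """Digamma for x > 0: recurrence to x >= 6, then asymptotic series."""
    result = 0.0
    while x < 10.0:
        result -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    result += (
        math.log(x)
        - 0.5 * inv
        - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0))
    )
    return result


@njit(cache=True)
def _softplus(eta: float) -> float:
    if eta > 0.0:
        return eta + math.log1p(math.exp(-eta))
    return math.log1p(math.exp(eta))


@njit(cache=True)
def joint_logp_grad(
    v,
    y,            # (D, J) latent mode; (0, 0) otherwise
    obs,          # (D, J) float mask
    y_cont,       # (D,) observed mode; (0,) otherwise
    W0,           # (D, K)
    mother,       # (D,)
    fam_idx,      # (D,) int64
    x_obs,        # (D, 4) predictor block, 0 placeholder at missing
    miss_d,       # (M,) int64 row of each missing x entry
    miss_j,       # (M,) int64 col of each missing x entry
    base_col,     # (4,) int64, design column of x[:, j] or -1
    inter_col,    # (4,) int64, design column of x[:, j]*mother or -1
    idx,          # (13,) int64 block starts, -1 if absent (see model.py)
    flags,        # (8,) bool: latent, use_u, free_tau, free_sigma, t_like,
                  #            free_nu, anchor, pred_model
    consts,       # (10,) float64: fix_sigma, fix_tau, fix_nu, coef_sd,
                  #   anchor_sd, loc_sd, disc_shape, disc_rate, disc_cap, tdf_rate
):
    latent, use_u, free_tau, free_sigma, t_like, free_nu, anchor, pred_model = (
        flags[0], flags[1], flags[2], flags[3], flags[4], flags[5], flags[6], flags[7]
    )
    (i_theta, i_u, i_ltau, i_b, i_lsig, i_nu, i_araw, i_braw, i_mub, i_lsb,
     i_mux, i_lch, i_xmiss) = (idx[0], idx[1], idx[2], idx[3], idx[4], idx[5],
                               idx[6], idx[7], idx[8], idx[9], idx[10], idx[11], idx[12])
    (fix_sigma, fix_tau, fix_nu, coef_sd, anchor_sd, loc_sd, disc_shape,
     disc_rate, disc_cap, tdf_rate) = (consts[0], consts[1], consts[2], consts[3],
                                       consts[4], consts[5], consts[6], consts[7],
                                       consts[8], consts[9])
    D = W0.shape[0]
    K = W0.shape[1]
    J = y.shape[1]
    M = miss_d.shape[0]

    grad = np.zeros(v.shape[0])
    lp = 0.0

    sigma = math.exp(v[i_lsig]) if free_sigma else fix_sigma
    tau = 0.0
    if use_u:
        tau = math.exp(v[i_ltau]) if free_tau else fix_tau
    nu = 0.0
    gshift = 0.0
    if t_like:
        if free_nu:
            gshift = math.exp(v[i_nu])
            nu = 1.0 + gshift
        else:
            nu = fix_nu

    # --- design with missing-x entries filled in -----------------------------
    if M > 0:
        W = W0.copy()
        x = x_obs.copy()
        for t in range(M):
            d = miss_d[t]
            j = miss_j[t]
            val = v[i_xmiss + t]
            x[d, j] = val
            if base_col[j] >= 0:
                W[d, base_col[j]] = val
            if inter_col[j] >= 0:
                W[d, inter_col[j]] = val * mother[d]
    else:
        W = W0
        x = x_obs

    # linear predictor
    m = np.zeros(D)
    for d in range(D):
        acc = 0.0
        for k in range(K):
            acc += W[d, k] * v[i_b + k]
        if use_u:
            acc += tau * v[i_u + fam_idx[d]]
        m[d] = acc

    # --- structural likelihood ----------------------------------------------
    dm = np.zeros(D)
    dsigma = 0.0
    dnu = 0.0
    if t_like:
        lp += D * (
            math.lgamma((nu + 1.0) / 2.0)
            - math.lgamma(nu / 2.0)
            - 0.5 * math.log(nu * math.pi)
            - math.log(sigma)
        )
        dg_half = 0.5 * (_digamma((nu + 1.0) / 2.0) - _digamma(nu / 2.0) - 1.0 / nu)
    for d in range(D):
        th = v[i_theta + d] if latent else y_cont[d]
        z = (th - m[d]) / sigma
        z2 = z * z
        if t_like:
            w = (nu + 1.0) / (nu + z2)
            lp += -(nu + 1.0) / 2.0 * math.log1p(z2 / nu)
            dth = -w * z / sigma
            dsigma += (w * z2 - 1.0) / sigma
            if free_nu:
                dnu += dg_half + 0.5 * (-math.log1p(z2 / nu) + w * z2 / nu)
        else:
            lp += -0.5 * z2 - math.log(sigma)
            dth = -z / sigma
            dsigma += (z2 - 1.0) / sigma
        dm[d] = -dth
        if latent:
            grad[i_theta + d] += dth

    # scatter dm into b, u, x_miss
    for d in range(D):
        for k in range(K):
            grad[i_b + k] += W[d, k] * dm[d]
    if use_u:
        dtau = 0.0
        for d in range(D):
            f = fam_idx[d]
            grad[i_u + f] += tau * dm[d]
            dtau += dm[d] * v[i_u + f]
        if free_tau:
            grad[i_ltau] += tau * (dtau - 4.0 * tau / (3.0 + tau * tau)) + 1.0
            lp += -2.0 * math.log1p(tau * tau / 3.0) + v[i_ltau]
        # u_raw ~ N(0,1)
        nF = 0
        for d in range(D):
            if fam_idx[d] + 1 > nF:
                nF = fam_idx[d] + 1
        for f in range(nF):
            lp += -0.5 * v[i_u + f] * v[i_u + f]
            grad[i_u + f] += -v[i_u + f]
    if M > 0:
        for t in range(M):
            d = miss_d[t]
            j = miss_j[t]
            acc = 0.0
            if base_col[j] >= 0:
                acc += dm[d] * v[i_b + base_col[j]]
            if inter_col[j] >= 0:
                acc += dm[d] * v[i_b + inter_col[j]] * mother[d]
            grad[i_xmiss + t] += acc

    if free_sigma:
        grad[i_lsig] += sigma * (dsigma - 4.0 * sigma / (3.0 + sigma * sigma)) + 1.0
        lp += -2.0 * math.log1p(sigma * sigma / 3.0) + v[i_lsig]
    if t_like and free_nu:
        lp += 2.0 * math.log(gshift) - tdf_rate * gshift
        grad[i_nu] += gshift * (dnu - tdf_rate) + 2.0

    # --- coefficient priors ---------------------------------------------------
    for k in range(K):
        b = v[i_b + k]
        lp += -0.5 * (b / coef_sd) ** 2
        grad[i_b + k] += -b / (coef_sd * coef_sd)

    # --- measurement layer ------------------------------------------------------
    if latent:
        if anchor:
            for d in range(D):
                th = v[i_theta + d]
                lp += -0.5 * (th / anchor_sd) ** 2
                grad[i_theta + d] += -th / (anchor_sd * anchor_sd)

        sigma_beta = math.exp(v[i_lsb])
        mu_beta = v[i_mub]
        for j in range(J):
            araw = v[i_araw + j]
            s = 1.0 / (1.0 + math.exp(-araw))
            alpha = disc_cap * s
            beta = mu_beta + sigma_beta * v[i_braw + j]
            dalpha = 0.0
            dbeta = 0.0
            for d in range(D):
                if obs[d, j] > 0.0:
                    dev = v[i_theta + d] - beta
                    eta = alpha * dev
                    lp += y[d, j] * eta - _softplus(eta)
                    r = y[d, j] - 1.0 / (1.0 + math.exp(-eta))
                    grad[i_theta + d] += alpha * r
                    dalpha += dev * r
                    dbeta += -alpha * r
            # discrimination prior + cap Jacobian
            dalpha_draw = alpha * (1.0 - alpha / disc_cap)
            lp += (disc_shape - 1.0) * math.log(alpha) - disc_rate * alpha
            lp += math.log(alpha) + math.log1p(-alpha / disc_cap)
            grad[i_araw + j] += (
                dalpha + (disc_shape - 1.0) / alpha - disc_rate
            ) * dalpha_draw + (1.0 - 2.0 * alpha / disc_cap)
            # hierarchical difficulty
            braw = v[i_braw + j]
            lp += -0.5 * braw * braw
            grad[i_braw + j] += sigma_beta * dbeta - braw
            grad[i_mub] += dbeta
            grad[i_lsb] += sigma_beta * dbeta * braw
        grad[i_mub] += -mu_beta / (loc_sd * loc_sd)
        lp += -0.5 * (mu_beta / loc_sd) ** 2
        lp += -2.0 * math.log1p(sigma_beta * sigma_beta / 3.0) + v[i_lsb]
        grad[i_lsb] += -4.0 * sigma_beta * sigma_beta / (3.0 + sigma_beta * sigma_beta) + 1.0

    # --- multivariate normal predictor block -----------------------------------
    if pred_model:
        L = np.zeros((4, 4))
        t = 0
        for i in range(4):
            for j in range(i + 1):
                if i == j:
                    L[i, j] = math.exp(v[i_lch + t])
                else:
                    L[i, j] = v[i_lch + t]
                t += 1
        # solve and accumulate
        sumA = np.zeros(4)
        AAT = np.zeros((4, 4))
        zz = 0.0
        Acols = np.zeros((4, D))
        for d in range(D):
            z0 = (x[d, 0] - v[i_mux + 0]) / L[0, 0]
            z1 = (x[d, 1] - v[i_mux + 1] - L[1, 0] * z0) / L[1, 1]
            z2 = (x[d, 2] - v[i_mux + 2] - L[2, 0] * z0 - L[2, 1] * z1) / L[2, 2]
            z3 = (x[d, 3] - v[i_mux + 3] - L[3, 0] * z0 - L[3, 1] * z1 - L[3, 2] * z2) / L[3, 3]
            zz += z0 * z0 + z1 * z1 + z2 * z2 + z3 * z3
            a3 = z3 / L[3, 3]
            a2 = (z2 - L[3, 2] * a3) / L[2, 2]
            a1 = (z1 - L[2, 1] * a2 - L[3, 1] * a3) / L[1, 1]
            a0 = (z0 - L[1, 0] * a1 - L[2, 0] * a2 - L[3, 0] * a3) / L[0, 0]
            Acols[0, d] = a0
            Acols[1, d] = a1
            Acols[2, d] = a2
            Acols[3, d] = a3
            sumA[0] += a0
            sumA[1] += a1
            sumA[2] += a2
            sumA[3] += a3
        for i in range(4):
            for j in range(4):
                acc = 0.0
                for d in range(D):
                    acc += Acols[i, d] * Acols[j, d]
                AAT[i, j] = acc
        logdet = 0.0
        for i in range(4):
            logdet += math.log(L[i, i])
        lp += -D * logdet - 0.5 * zz
        for i in range(4):
            grad[i_mux + i] += sumA[i]
        if M > 0:
            for t2 in range(M):
                grad[i_xmiss + t2] += -Acols[miss_j[t2], miss_d[t2]]
        # GL = (A A') L, lower triangle; diag corrected by -D / L_ii
        t = 0
        for i in range(4):
            for j in range(i + 1):
                gl = 0.0
                for k in range(4):
                    gl += AAT[i, k] * L[k, j]
                if i == j:
                    gl -= D / L[i, i]
                    dprior = -4.0 * L[i, i] / (3.0 + L[i, i] * L[i, i])
                    grad[i_lch + t] += (gl + dprior) * L[i, i] + 1.0
                    lp += -2.0 * math.log1p(L[i, i] * L[i, i] / 3.0) + v[i_lch + t]
                else:
                    grad[i_lch + t] += gl - L[i, j]
                    lp += -0.5 * L[i, j] * L[i, j]
                t += 1
        for i in range(4):
            mu = v[i_mux + i]
            lp += -0.5 * mu * mu
            grad[i_mux + i] += -mu
    return lp, grad
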