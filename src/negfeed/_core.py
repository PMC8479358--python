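"""Numba kernels: Euler-Maruyama simulation and the delay-adapted Kalman filter.

State layout for the filter
---------------------------
The filter carries a joint Gaussian over the window of discretised states
``x_{t-d}, ..., x_t`` where ``d = round(tau / dt_filter)`` and each state is
the pair ``[m, p]``.  With ``L = d + 1`` states the window mean is an
``(L, 2)`` array (oldest first) and the window covariance a ``(2L, 2L)``
matrix in which state ``i`` occupies flat indices ``2i`` (mRNA) and
``2i + 1`` (protein).

One prediction fine-step advances the window by ``dt_filter``:

    m' = m + dt (alpha_m f(p_delayed) - mu_m m)
    p' = p + dt (alpha_p m - mu_p p)

with the new state linear in the old window through

    x' = A x_current + B x_delayed + const + noise,
    A = [[1 - dt mu_m, 0], [dt alpha_p, 1 - dt mu_p]],
    B = [[0, dt alpha_m f'(pd)], [0, 0]],
    Q = dt diag(alpha_m f(pd) + mu_m m,  alpha_p m + mu_p p),

all coefficients evaluated at the current window mean (first-order
linearisation of the Hill term at the filtered delayed-protein mean).
When ``d == 0`` the delayed state coincides with the current state; the flat
index of the delayed protein (1) then equals the current protein index, so
the same update formulas apply without special-casing.

The update step conditions the *entire* window jointly on the scalar
observation ``y = p_current + eps``: a rank-one correction through the
covariance column of the current protein.

Gradient recursion: for each requested parameter the kernel co-propagates
``d(rho)/d(theta)`` and ``d(P)/d(theta)`` through the exact chain rule of the
implemented (linearised) filter, including the dependence of A, B and Q on
the window mean, and accumulates the derivative of each per-observation
Gaussian log-density.  Parameter codes: 0 = P0, 1 = h, 2 = alpha_m,
3 = alpha_p, 4 = mu_m, 5 = mu_p (natural coordinates; the delay is handled
one level up by interpolation across grid delays).
"""

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def hill_val(p, P0, h):
    """Hill repression factor f(p) = 1 / (1 + (p/P0)^h), clipped for p <= 0."""
    if p <= 0.0:
        return 1.0
    lu = h * (np.log(p) - np.log(P0))
    if lu > 300.0:
        lu = 300.0
    return 1.0 / (1.0 + np.exp(lu))


@njit(cache=True)
def hill_terms(p, P0, h):
    """Hill factor with the partial derivatives needed by the filter.

    Returns ``(f, fp, fpp, fP0, fh, fpP0, fph)`` where ``fp``/``fpp`` are the
    first/second derivatives in the protein argument and the remaining terms
    are cross-partials with respect to P0 and h.
    """
    if p <= 0.0:
        return 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    lr = np.log(p) - np.log(P0)
    lu = h * lr
    if lu > 300.0:
        lu = 300.0
    u = np.exp(lu)
    s = 1.0 + u
    s2 = s * s
    s3 = s2 * s
    f = 1.0 / s
    up = h * u / p
    upp = h * (h - 1.0) * u / (p * p)
    uP0 = -h * u / P0
    uh = u * lr
    fp = -up / s2
    fpp = -upp / s2 + 2.0 * up * up / s3
    fP0 = -uP0 / s2
    fh = -uh / s2
    upP0 = -h * h * u / (p * P0)
    uph = (u / p) * (1.0 + h * lr)
    fpP0 = -upP0 / s2 + 2.0 * up * uP0 / s3
    fph = -uph / s2 + 2.0 * up * uh / s3
    return f, fp, fpp, fP0, fh, fpP0, fph


@njit(cache=True)
def sim_em(dt, d, P0, h, mu_m, mu_p, al_m, al_p, hist_m, hist_p, noise, n_steps, stochastic):
    """Euler-Maruyama path of the delayed chemical Langevin equations.

    ``hist_m``/``hist_p`` hold the initial history on ``[-d*dt, 0]``
    (length ``d + 1``); ``noise`` is a ``(2, n_steps)`` array of standard
    normals (ignored when ``stochastic`` is false).  Returns the path on
    ``[0, n_steps*dt]`` including both endpoints.  Negative copy numbers are
    clipped to zero and the square-root noise amplitudes use ``max(., 0)``
    inside the root.
    """
    nh = hist_m.shape[0]
    N = nh + n_steps
    m = np.empty(N)
    p = np.empty(N)
    for i in range(nh):
        m[i] = hist_m[i]
        p[i] = hist_p[i]
    for i in range(nh - 1, N - 1):
        pd = p[i - d]
        f = hill_val(pd, P0, h)
        rm_in = al_m * f
        rm_out = mu_m * m[i]
        rp_in = al_p * m[i]
        rp_out = mu_p * p[i]
        dm = dt * (rm_in - rm_out)
        dp = dt * (rp_in - rp_out)
        if stochastic:
            vm = rm_in + rm_out
            vp = rp_in + rp_out
            if vm < 0.0:
                vm = 0.0
            if vp < 0.0:
                vp = 0.0
            dm += np.sqrt(dt * vm) * noise[0, i - nh + 1]
            dp += np.sqrt(dt * vp) * noise[1, i - nh + 1]
        mv = m[i] + dm
        pv = p[i] + dp
        m[i + 1] = mv if mv > 0.0 else 0.0
        p[i + 1] = pv if pv > 0.0 else 0.0
    return m[nh - 1:], p[nh - 1:]


@njit(cache=True)
def kalman_pass(y, z, dtf, d, P0, h, mu_m, mu_p, al_m, al_p, sig_eps,
                codes, rho0, var0, drho0, dvar0):
    """One full forward pass of the delay-adapted Kalman filter.

    Parameters
    ----------
    y : observations (length n), one every ``z`` fine steps of size ``dtf``.
    d : delay in fine steps (window has ``d + 1`` state pairs).
    codes : int64 array of parameter codes for which derivative recursions
        are co-propagated (may be empty).
    rho0, var0 : initial per-state mean and diagonal variances ``[m, p]``.
    drho0, dvar0 : ``(K, 2)`` derivatives of the initial mean/variances.

    Returns
    -------
    ok, loglik, per_obs, pred_mean, pred_var, grad, mrna_avg, dmrna_avg
        ``mrna_avg`` is the time-average over observation times of the
        filtered (posterior) mRNA mean of the current state, used by the
        mRNA-snapshot augmentation; ``dmrna_avg`` its gradient.
    """
    n = y.shape[0]
    K = codes.shape[0]
    L = d + 1
    W = 2 * L
    rho = np.empty((L, 2))
    P = np.zeros((W, W))
    Pn = np.zeros((W, W))
    drho = np.zeros((K, L, 2))
    dP = np.zeros((K, W, W))
    dPn = np.zeros((K, W, W))
    for i in range(L):
        rho[i, 0] = rho0[0]
        rho[i, 1] = rho0[1]
        P[2 * i, 2 * i] = var0[0]
        P[2 * i + 1, 2 * i + 1] = var0[1]
    for k in range(K):
        for i in range(L):
            drho[k, i, 0] = drho0[k, 0]
            drho[k, i, 1] = drho0[k, 1]
            dP[k, 2 * i, 2 * i] = dvar0[k, 0]
            dP[k, 2 * i + 1, 2 * i + 1] = dvar0[k, 1]
    crm = np.empty(W)
    crp = np.empty(W)
    dcrm = np.empty((K, W))
    dcrp = np.empty((K, W))
    per_obs = np.zeros(n)
    pred_mean = np.zeros(n)
    pred_var = np.zeros(n)
    grad = np.zeros(K)
    dmr_sum = np.zeros(K)
    loglik = 0.0
    mr_sum = 0.0
    tm = W - 2
    tp = W - 1
    dpi = 1  # flat index of the delayed protein (== tp when d == 0)
    ok = 1
    for j in range(n):
        if j > 0:
            for _step in range(z):
                m = rho[L - 1, 0]
                p = rho[L - 1, 1]
                pd = rho[0, 1]
                f, fp, fpp, fP0, fh, fpP0, fph = hill_terms(pd, P0, h)
                am_f = al_m * f
                nm = m + dtf * (am_f - mu_m * m)
                npv = p + dtf * (al_p * m - mu_p * p)
                a00 = 1.0 - dtf * mu_m
                a10 = dtf * al_p
                a11 = 1.0 - dtf * mu_p
                b01 = dtf * al_m * fp
                qm_raw = am_f + mu_m * m
                qp_raw = al_p * m + mu_p * p
                qm = dtf * qm_raw if qm_raw > 0.0 else 0.0
                qp = dtf * qp_raw if qp_raw > 0.0 else 0.0
                s_mm = (a00 * a00 * P[tm, tm] + 2.0 * a00 * b01 * P[tm, dpi]
                        + b01 * b01 * P[dpi, dpi] + qm)
                s_mp = (a00 * a10 * P[tm, tm] + a00 * a11 * P[tm, tp]
                        + b01 * a10 * P[dpi, tm] + b01 * a11 * P[dpi, tp])
                s_pp = (a10 * a10 * P[tm, tm] + 2.0 * a10 * a11 * P[tm, tp]
                        + a11 * a11 * P[tp, tp] + qp)
                for c in range(2, W):
                    crm[c] = a00 * P[tm, c] + b01 * P[dpi, c]
                    crp[c] = a10 * P[tm, c] + a11 * P[tp, c]
                for k in range(K):
                    code = codes[k]
                    dpd = drho[k, 0, 1]
                    if code == 0:
                        f_dir = fP0
                        fp_dir = fpP0
                    elif code == 1:
                        f_dir = fh
                        fp_dir = fph
                    else:
                        f_dir = 0.0
                        fp_dir = 0.0
                    df = f_dir + fp * dpd
                    dfp = fp_dir + fpp * dpd
                    dam = 1.0 if code == 2 else 0.0
                    dap = 1.0 if code == 3 else 0.0
                    dmm = 1.0 if code == 4 else 0.0
                    dmp = 1.0 if code == 5 else 0.0
                    dm_ = drho[k, L - 1, 0]
                    dp_ = drho[k, L - 1, 1]
                    dam_f = dam * f + al_m * df
                    dnm = dm_ + dtf * (dam_f - dmm * m - mu_m * dm_)
                    dnp = dp_ + dtf * (dap * m + al_p * dm_ - dmp * p - mu_p * dp_)
                    da00 = -dtf * dmm
                    da10 = dtf * dap
                    da11 = -dtf * dmp
                    db01 = dtf * (dam * fp + al_m * dfp)
                    dqm = dtf * (dam_f + dmm * m + mu_m * dm_) if qm_raw > 0.0 else 0.0
                    dqp = dtf * (dap * m + al_p * dm_ + dmp * p + mu_p * dp_) if qp_raw > 0.0 else 0.0
                    dPk = dP[k]
                    ds_mm = (2.0 * a00 * da00 * P[tm, tm] + a00 * a00 * dPk[tm, tm]
                             + 2.0 * (da00 * b01 + a00 * db01) * P[tm, dpi]
                             + 2.0 * a00 * b01 * dPk[tm, dpi]
                             + 2.0 * b01 * db01 * P[dpi, dpi] + b01 * b01 * dPk[dpi, dpi]
                             + dqm)
                    ds_mp = ((da00 * a10 + a00 * da10) * P[tm, tm] + a00 * a10 * dPk[tm, tm]
                             + (da00 * a11 + a00 * da11) * P[tm, tp] + a00 * a11 * dPk[tm, tp]
                             + (db01 * a10 + b01 * da10) * P[dpi, tm] + b01 * a10 * dPk[dpi, tm]
                             + (db01 * a11 + b01 * da11) * P[dpi, tp] + b01 * a11 * dPk[dpi, tp])
                    ds_pp = (2.0 * a10 * da10 * P[tm, tm] + a10 * a10 * dPk[tm, tm]
                             + 2.0 * (da10 * a11 + a10 * da11) * P[tm, tp]
                             + 2.0 * a10 * a11 * dPk[tm, tp]
                             + 2.0 * a11 * da11 * P[tp, tp] + a11 * a11 * dPk[tp, tp]
                             + dqp)
                    for c in range(2, W):
                        dcrm[k, c] = (da00 * P[tm, c] + a00 * dPk[tm, c]
                                      + db01 * P[dpi, c] + b01 * dPk[dpi, c])
                        dcrp[k, c] = (da10 * P[tm, c] + a10 * dPk[tm, c]
                                      + da11 * P[tp, c] + a11 * dPk[tp, c])
                    dPnk = dPn[k]
                    for a in range(W - 2):
                        for b in range(W - 2):
                            dPnk[a, b] = dPk[a + 2, b + 2]
                    for b in range(W - 2):
                        dPnk[W - 2, b] = dcrm[k, b + 2]
                        dPnk[b, W - 2] = dcrm[k, b + 2]
                        dPnk[W - 1, b] = dcrp[k, b + 2]
                        dPnk[b, W - 1] = dcrp[k, b + 2]
                    dPnk[W - 2, W - 2] = ds_mm
                    dPnk[W - 2, W - 1] = ds_mp
                    dPnk[W - 1, W - 2] = ds_mp
                    dPnk[W - 1, W - 1] = ds_pp
                    for i in range(L - 1):
                        drho[k, i, 0] = drho[k, i + 1, 0]
                        drho[k, i, 1] = drho[k, i + 1, 1]
                    drho[k, L - 1, 0] = dnm
                    drho[k, L - 1, 1] = dnp
                for a in range(W - 2):
                    for b in range(W - 2):
                        Pn[a, b] = P[a + 2, b + 2]
                for b in range(W - 2):
                    Pn[W - 2, b] = crm[b + 2]
                    Pn[b, W - 2] = crm[b + 2]
                    Pn[W - 1, b] = crp[b + 2]
                    Pn[b, W - 1] = crp[b + 2]
                Pn[W - 2, W - 2] = s_mm
                Pn[W - 2, W - 1] = s_mp
                Pn[W - 1, W - 2] = s_mp
                Pn[W - 1, W - 1] = s_pp
                tmpP = P
                P = Pn
                Pn = tmpP
                tmpdP = dP
                dP = dPn
                dPn = tmpdP
                for i in range(L - 1):
                    rho[i, 0] = rho[i + 1, 0]
                    rho[i, 1] = rho[i + 1, 1]
                rho[L - 1, 0] = nm
                rho[L - 1, 1] = npv
        # --- likelihood of observation j from the predictive window ---
        S = P[tp, tp] + sig_eps
        if not np.isfinite(S) or S <= 0.0:
            ok = 0
            break
        v = y[j] - rho[L - 1, 1]
        ll = -0.5 * (LOG2PI + np.log(S)) - 0.5 * v * v / S
        per_obs[j] = ll
        pred_mean[j] = rho[L - 1, 1]
        pred_var[j] = S
        loglik += ll
        for k in range(K):
            dS = dP[k, tp, tp]
            dv = -drho[k, L - 1, 1]
            grad[k] += -0.5 * dS / S - v * dv / S + 0.5 * v * v * dS / (S * S)
        # --- update: condition the whole window on y_j (rank-one) ---
        for a in range(W):
            crm[a] = P[a, tp]
        coef = v / S
        for k in range(K):
            dPk = dP[k]
            dS = dPk[tp, tp]
            dv = -drho[k, L - 1, 1]
            dcoef = dv / S - v * dS / (S * S)
            for a in range(W):
                dcrm[k, a] = dPk[a, tp]
            for i in range(L):
                drho[k, i, 0] += dcrm[k, 2 * i] * coef + crm[2 * i] * dcoef
                drho[k, i, 1] += dcrm[k, 2 * i + 1] * coef + crm[2 * i + 1] * dcoef
            for a in range(W):
                for b in range(W):
                    dPk[a, b] += (-(dcrm[k, a] * crm[b] + crm[a] * dcrm[k, b]) / S
                                  + crm[a] * crm[b] * dS / (S * S))
        for i in range(L):
            rho[i, 0] += crm[2 * i] * coef
            rho[i, 1] += crm[2 * i + 1] * coef
        for a in range(W):
            for b in range(W):
                P[a, b] -= crm[a] * crm[b] / S
        for a in range(W):
            for b in range(a + 1, W):
                sym = 0.5 * (P[a, b] + P[b, a])
                P[a, b] = sym
                P[b, a] = sym
        mr_sum += rho[L - 1, 0]
        for k in range(K):
            dmr_sum[k] += drho[k, L - 1, 0]
    return (ok, loglik, per_obs, pred_mean, pred_var, grad,
            mr_sum / n, dmr_sum / n)
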