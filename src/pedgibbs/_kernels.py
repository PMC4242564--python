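"""Numba kernels for the single-site Gibbs sampler.

Layout shared by all kernels: the location-effect vector ``theta`` of
length p stacks

* ``nf`` systematic ("fixed", flat-prior) effects,
* ``ngen`` pedigree-structured genetic blocks of ``N`` effects each
  (group 0 = direct additive, group 1 = maternal genetic when present),
  with prior precision ``Ginv (x) Ainv``,
* ``qc`` iid maternal permanent-environment effects.

The design is stored column-compressed (``colptr/colrow/colval``): for each
effect, the records it touches and the design values.  The residual vector
``e = response - design @ theta`` is maintained incrementally and refreshed
from scratch every ``check_every`` iterations (drift is reported).
"""

import numpy as np
from numba import njit

VAR_FLOOR = 1e-10


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def rtnorm_pos(mu):
    """Draw from N(mu, 1) truncated to (0, inf); robust for mu down to -8 and
    beyond (exponential rejection in the far tail)."""
    a = -mu  # standard-normal draw must exceed a
    if a <= 0.45:
        while True:
            x = np.random.standard_normal()
            if x > a:
                return mu + x
    else:
        alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
        while True:
            z = a + np.random.standard_exponential() / alpha
            rho = np.exp(-0.5 * (z - alpha) * (z - alpha))
            if np.random.random_sample() <= rho:
                return mu + z


@njit(cache=True)
def rtnorm_interval(mu, sd, bound):
    """Draw from N(mu, sd^2) truncated to [-bound, bound].

    The generic case (interval covers the bulk) uses simple rejection; a
    mean pushed against or beyond a bound (complete separation of a fixed
    effect on the liability scale) reduces to a one-sided draw from the
    near boundary, the far boundary being many sd away.
    """
    a = (-bound - mu) / sd
    b = (bound - mu) / sd
    if a < -4.0 and b > 4.0:
        return mu + sd * np.random.standard_normal()
    if a <= 0.0 <= b:
        while True:
            z = np.random.standard_normal()
            if a <= z <= b:
                return mu + sd * z
    if a > 0.0:
        while True:
            z = rtnorm_pos(-a) + a  # standard normal conditioned on z > a
            if z <= b:
                return mu + sd * z
    while True:
        z = -(rtnorm_pos(b) - b)  # z < b by mirror symmetry
        if z >= a:
            return mu + sd * z


@njit(cache=True)
def sample_liabilities_inplace(y01, l, e):
    """Truncated-normal liability update; keeps e = l - predictor consistent."""
    n = y01.shape[0]
    for r in range(n):
        mu = l[r] - e[r]
        if y01[r] == 1:
            lnew = rtnorm_pos(mu)
        else:
            lnew = -rtnorm_pos(-mu)
        e[r] += lnew - l[r]
        l[r] = lnew


@njit(cache=True)
def update_effects(
    theta,
    e,
    colptr,
    colrow,
    colval,
    xtx,
    nf,
    ngen,
    N,
    ai_ptr,
    ai_idx,
    ai_val,
    ai_diag,
    Ginv,
    sig_c,
    sig_e,
    dam_ped_pos,
    fixed_bound,
):
    """One full sweep over all location effects.

    Systematic effects use scalar draws from their Gaussian full
    conditionals.  With two correlated genetic blocks the pair (u_i, m_i)
    of each pedigree member is drawn jointly from its bivariate-normal
    full conditional: scalar updates mix pathologically there, because a
    sampled genetic correlation near +-1 makes u_i ~ m_i absorbing.  The
    pair's data cross-product is zero (no record has the same individual
    as calf and dam), so the joint precision is cheap.

    The maternal genetic and permanent-environment effects of one dam
    share identical incidence (every record of that dam), which makes
    their scalar conditionals nearly degenerate and lets one absorb the
    other; when both blocks are present each (m_dam, c_dam) pair is
    therefore also drawn jointly in a second pass.  The residual is
    updated incrementally after each draw.
    """
    p = theta.shape[0]
    goff = nf
    coff = nf + ngen * N
    for j in range(nf):
        _scalar_draw(theta, e, colptr, colrow, colval, xtx, j, 0.0, 0.0, sig_e,
                     fixed_bound)
    if ngen == 1:
        for i in range(N):
            j = goff + i
            num0 = 0.0
            for a in range(ai_ptr[i], ai_ptr[i + 1]):
                k = ai_idx[a]
                if k != i:
                    num0 -= Ginv[0, 0] * ai_val[a] * theta[goff + k]
            _scalar_draw(
                theta, e, colptr, colrow, colval, xtx, j,
                Ginv[0, 0] * ai_diag[i], num0, sig_e, np.inf,
            )
    elif ngen == 2:
        for i in range(N):
            ju = goff + i
            jm = goff + N + i
            # prior mean contribution from relatives (k != i), both blocks
            su0 = 0.0  # sum Ai_ik * u_k
            su1 = 0.0  # sum Ai_ik * m_k
            for a in range(ai_ptr[i], ai_ptr[i + 1]):
                k = ai_idx[a]
                if k != i:
                    su0 += ai_val[a] * theta[goff + k]
                    su1 += ai_val[a] * theta[goff + N + k]
            r0 = -(Ginv[0, 0] * su0 + Ginv[0, 1] * su1)
            r1 = -(Ginv[1, 0] * su0 + Ginv[1, 1] * su1)
            # data parts
            xeu = 0.0
            for idx in range(colptr[ju], colptr[ju + 1]):
                xeu += colval[idx] * e[colrow[idx]]
            xem = 0.0
            for idx in range(colptr[jm], colptr[jm + 1]):
                xem += colval[idx] * e[colrow[idx]]
            b0 = (xeu + xtx[ju] * theta[ju]) / sig_e + r0
            b1 = (xem + xtx[jm] * theta[jm]) / sig_e + r1
            aii = ai_diag[i]
            p00 = xtx[ju] / sig_e + Ginv[0, 0] * aii
            p01 = Ginv[0, 1] * aii
            p11 = xtx[jm] / sig_e + Ginv[1, 1] * aii
            # solve and draw from N(P^-1 b, P^-1) via Cholesky of P
            l00 = np.sqrt(p00)
            l10 = p01 / l00
            l11 = np.sqrt(max(p11 - l10 * l10, 1e-12 * p11))
            # mean: solve L L' mu = b
            z0 = b0 / l00
            z1 = (b1 - l10 * z0) / l11
            mu1 = z1 / l11
            mu0 = (z0 - l10 * mu1) / l00
            # noise: solve L' x = standard normal
            g0 = np.random.standard_normal()
            g1 = np.random.standard_normal()
            x1 = g1 / l11
            x0 = (g0 - l10 * x1) / l00
            new_u = mu0 + x0
            new_m = mu1 + x1
            du = new_u - theta[ju]
            if du != 0.0:
                for idx in range(colptr[ju], colptr[ju + 1]):
                    e[colrow[idx]] -= colval[idx] * du
            dm = new_m - theta[jm]
            if dm != 0.0:
                for idx in range(colptr[jm], colptr[jm + 1]):
                    e[colrow[idx]] -= colval[idx] * dm
            theta[ju] = new_u
            theta[jm] = new_m
    if ngen == 2 and p > coff:
        # joint (m_dam, c_dam) pairs: shared incidence, cross-product = xtx
        for k in range(p - coff):
            i = dam_ped_pos[k]
            jm = goff + N + i
            jc = coff + k
            A = xtx[jc]
            su0 = 0.0
            su1 = 0.0
            for a in range(ai_ptr[i], ai_ptr[i + 1]):
                kk = ai_idx[a]
                if kk != i:
                    su0 += ai_val[a] * theta[goff + kk]
                    su1 += ai_val[a] * theta[goff + N + kk]
            aii = ai_diag[i]
            # m's prior rhs conditions on u_i as well (it is not in this pair)
            r1 = -(Ginv[1, 0] * (su0 + aii * theta[goff + i]) + Ginv[1, 1] * su1)
            xe = 0.0
            for idx in range(colptr[jc], colptr[jc + 1]):
                xe += colval[idx] * e[colrow[idx]]
            common = (xe + A * (theta[jm] + theta[jc])) / sig_e
            b0 = common + r1
            b1 = common
            p00 = A / sig_e + Ginv[1, 1] * aii
            p01 = A / sig_e
            p11 = A / sig_e + 1.0 / sig_c
            l00 = np.sqrt(p00)
            l10 = p01 / l00
            l11 = np.sqrt(max(p11 - l10 * l10, 1e-12 * p11))
            z0 = b0 / l00
            z1 = (b1 - l10 * z0) / l11
            mu1 = z1 / l11
            mu0 = (z0 - l10 * mu1) / l00
            g0 = np.random.standard_normal()
            g1 = np.random.standard_normal()
            x1 = g1 / l11
            x0 = (g0 - l10 * x1) / l00
            new_m = mu0 + x0
            new_c = mu1 + x1
            dsum = (new_m - theta[jm]) + (new_c - theta[jc])
            if dsum != 0.0:
                for idx in range(colptr[jc], colptr[jc + 1]):
                    e[colrow[idx]] -= colval[idx] * dsum
            theta[jm] = new_m
            theta[jc] = new_c
    else:
        for j in range(coff, p):
            _scalar_draw(
                theta, e, colptr, colrow, colval, xtx, j, 1.0 / sig_c, 0.0,
                sig_e, np.inf,
            )


@njit(cache=True)
def _scalar_draw(theta, e, colptr, colrow, colval, xtx, j, prior_prec, prior_num,
                 sig_e, bound):
    """Draw one scalar effect from its full conditional and update e.

    A finite ``bound`` gives the bounded-uniform prior of the systematic
    effects: the conditional is truncated to [-bound, bound], which stops
    the liability-scale escape of completely separated levels."""
    s = colptr[j]
    t = colptr[j + 1]
    xe = 0.0
    for idx in range(s, t):
        xe += colval[idx] * e[colrow[idx]]
    num = (xe + xtx[j] * theta[j]) / sig_e + prior_num
    prec = xtx[j] / sig_e + prior_prec
    cv = 1.0 / prec
    if np.isfinite(bound):
        new = rtnorm_interval(num * cv, np.sqrt(cv), bound)
    else:
        new = num * cv + np.random.standard_normal() * np.sqrt(cv)
    diff = new - theta[j]
    if diff != 0.0:
        for idx in range(s, t):
            e[colrow[idx]] -= colval[idx] * diff
    theta[j] = new


@njit(cache=True)
def genetic_quadratic_forms(theta, nf, ngen, N, ai_ptr, ai_idx, ai_val):
    """qf[g, h] = theta_g' Ainv theta_h for each pair of genetic groups."""
    qf = np.zeros((ngen, ngen))
    for i in range(N):
        for a in range(ai_ptr[i], ai_ptr[i + 1]):
            k = ai_idx[a]
            v = ai_val[a]
            for g in range(ngen):
                tg = theta[nf + g * N + i]
                for h in range(ngen):
                    qf[g, h] += tg * v * theta[nf + h * N + k]
    return qf


@njit(cache=True)
def draw_invwishart_2x2(psi00, psi01, psi11, df):
    """Draw G ~ InvWishart(Psi, df) for a 2x2 scale matrix via Bartlett on
    the Wishart of the inverse.  Returns (g00, g01, g11)."""
    # inverse of Psi
    det = psi00 * psi11 - psi01 * psi01
    if det < 1e-300:
        det = 1e-300
    ip00 = psi11 / det
    ip01 = -psi01 / det
    ip11 = psi00 / det
    # Cholesky of inv(Psi)
    l11 = np.sqrt(ip00)
    l21 = ip01 / l11
    l22 = np.sqrt(max(ip11 - l21 * l21, 1e-300))
    # Bartlett factor
    a11 = np.sqrt(np.random.chisquare(df))
    a21 = np.random.standard_normal()
    a22 = np.sqrt(np.random.chisquare(df - 1.0))
    # T = L @ A (lower triangular)
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    # W = T T' ~ Wishart(inv(Psi), df); G = inv(W)
    w00 = t11 * t11
    w01 = t11 * t21
    w11 = t21 * t21 + t22 * t22
    dw = w00 * w11 - w01 * w01
    if dw < 1e-300:
        dw = 1e-300
    return w11 / dw, -w01 / dw, w00 / dw


@njit(cache=True)
def sample_genetic_covariance(
    qf, N, ngen, joint, ev_prior_df, ev_prior_scale, g_prior_df, g_prior_scale
):
    """Sample the genetic (co)variance block given its quadratic forms.

    Scalar blocks draw (qf + max(v,0)*S) / chi2_{N + v} with the
    (v, S) = (ev_prior_df, ev_prior_scale) prior; the joint 2-block the
    inverse Wishart with df = N + g_prior_df and scale qf + max(df,0)*S*I.
    (v, S) = (-2, 0) / df = -(p+1) = -3 are the flat priors used on the
    continuous scale; positive (v, S) give the weakly-informative proper
    priors the threshold scale needs (see gibbs_core docs).  Non-PD joint
    draws are retried up to 10 times, then the correlation is clipped.
    """
    G = np.zeros((ngen, ngen))
    s_add = max(ev_prior_df, 0.0) * ev_prior_scale
    if ngen != 2 or not joint:
        for g in range(ngen):
            G[g, g] = max(
                (qf[g, g] + s_add) / np.random.chisquare(N + ev_prior_df),
                VAR_FLOOR,
            )
        return G
    df = N + g_prior_df
    psi_add = max(g_prior_df, 0.0) * g_prior_scale
    psi00 = qf[0, 0] + psi_add
    psi11 = qf[1, 1] + psi_add
    psi01 = qf[0, 1]
    g00 = g01 = g11 = 0.0
    ok = False
    for _ in range(10):
        g00, g01, g11 = draw_invwishart_2x2(psi00, psi01, psi11, df)
        if g00 > VAR_FLOOR and g11 > VAR_FLOOR and g00 * g11 - g01 * g01 > 0.0:
            ok = True
            break
    if not ok:
        g00 = max(g00, VAR_FLOOR)
        g11 = max(g11, VAR_FLOOR)
    # numerical bound: a correlation within rounding of +-1 makes the
    # conditional precision of the (u, m) pairs catastrophically
    # ill-conditioned, so the magnitude is capped just inside the boundary
    lim = 0.999 * np.sqrt(g00 * g11)
    if g01 > lim:
        g01 = lim
    elif g01 < -lim:
        g01 = -lim
    G[0, 0] = g00
    G[0, 1] = g01
    G[1, 0] = g01
    G[1, 1] = g11
    return G


@njit(cache=True)
def invert_g(G, ngen):
    Ginv = np.zeros((ngen, ngen))
    if ngen == 0:
        return Ginv
    if ngen == 1:
        Ginv[0, 0] = 1.0 / G[0, 0]
    else:
        det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
        if det < 1e-300:
            det = 1e-300
        Ginv[0, 0] = G[1, 1] / det
        Ginv[0, 1] = -G[0, 1] / det
        Ginv[1, 0] = -G[1, 0] / det
        Ginv[1, 1] = G[0, 0] / det
    return Ginv


@njit(cache=True)
def refresh_residual(resp, theta, colptr, colrow, colval, e):
    """Recompute e = resp - design @ theta from scratch; return max drift."""
    n = resp.shape[0]
    fresh = resp.copy()
    p = theta.shape[0]
    for j in range(p):
        tj = theta[j]
        if tj != 0.0:
            for idx in range(colptr[j], colptr[j + 1]):
                fresh[colrow[idx]] -= colval[idx] * tj
    drift = 0.0
    for r in range(n):
        d = abs(fresh[r] - e[r])
        if d > drift:
            drift = d
        e[r] = fresh[r]
    return drift


@njit(cache=True)
def run_chain(
    seed,
    y,
    is_threshold,
    nf,
    ngen,
    N,
    qc,
    colptr,
    colrow,
    colval,
    xtx,
    ai_ptr,
    ai_idx,
    ai_val,
    ai_diag,
    dam_ped_pos,
    chain_length,
    burn_in,
    thin,
    v_prior,
    s_prior,
    ev_prior_df,
    ev_prior_scale,
    g_prior_df,
    g_prior_scale,
    fixed_bound,
    joint_g,
    store_effects,
    check_every,
):
    """Full Gibbs chain.  Returns (var_out, eff_out, max_drift).

    var_out columns: sigma2_u, sigma2_m, sigma_um, sigma2_c, sigma2_e.
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = nf + ngen * N + qc
    coff = nf + ngen * N
    theta = np.zeros(p)

    if is_threshold:
        l = np.where(y > 0.5, 0.5, -0.5).astype(np.float64)
        resp = l
        sig_e = 1.0
        base_var = 1.0
    else:
        l = np.zeros(1)
        resp = y.astype(np.float64)
        base_var = max(np.var(resp), 1e-3)
        sig_e = base_var
    e = resp.copy()

    G = np.zeros((ngen, ngen))
    for g in range(ngen):
        G[g, g] = 0.1 * base_var
    Ginv = invert_g(G, ngen)
    sig_c = 0.1 * base_var if qc > 0 else 1.0

    y01 = (y > 0.5).astype(np.int64)
    n_saved = (chain_length - burn_in) // thin
    var_out = np.zeros((n_saved, 5))
    if store_effects:
        eff_out = np.zeros((n_saved, p))
    else:
        eff_out = np.zeros((1, 1))

    max_drift = 0.0
    k = 0
    for it in range(chain_length):
        if is_threshold:
            sample_liabilities_inplace(y01, l, e)
        update_effects(
            theta, e, colptr, colrow, colval, xtx,
            nf, ngen, N, ai_ptr, ai_idx, ai_val, ai_diag,
            Ginv, sig_c, sig_e, dam_ped_pos, fixed_bound,
        )
        qf = genetic_quadratic_forms(theta, nf, ngen, N, ai_ptr, ai_idx, ai_val)
        G = sample_genetic_covariance(
            qf, N, ngen, joint_g,
            ev_prior_df, ev_prior_scale, g_prior_df, g_prior_scale,
        )
        Ginv = invert_g(G, ngen)
        if qc > 0:
            cc = 0.0
            for j in range(coff, p):
                cc += theta[j] * theta[j]
            sig_c = max(
                (cc + max(ev_prior_df, 0.0) * ev_prior_scale)
                / np.random.chisquare(qc + ev_prior_df),
                VAR_FLOOR,
            )
        if not is_threshold:
            ee = 0.0
            for r in range(n):
                ee += e[r] * e[r]
            sig_e = max(
                (ee + max(v_prior, 0.0) * s_prior) / np.random.chisquare(n + v_prior),
                VAR_FLOOR,
            )
        if not np.isfinite(sig_e) or (ngen > 0 and not np.isfinite(G[0, 0])):
            raise RuntimeError("divergent sampler state (non-finite variance)")

        if (it + 1) % check_every == 0:
            drift = refresh_residual(resp, theta, colptr, colrow, colval, e)
            if drift > max_drift:
                max_drift = drift

        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            if ngen > 0:
                var_out[k, 0] = G[0, 0]
            if ngen > 1:
                var_out[k, 1] = G[1, 1]
                var_out[k, 2] = G[0, 1]
            var_out[k, 3] = sig_c if qc > 0 else 0.0
            var_out[k, 4] = sig_e
            if store_effects:
                for j in range(p):
                    eff_out[k, j] = theta[j]
            k += 1
    return var_out, eff_out, max_drift
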