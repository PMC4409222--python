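"""Compiled Gibbs-sweep kernels.

Everything here is numba-jitted and uses numba's global legacy-numpy RNG,
seeded explicitly through :func:`seed_rng` (or the ``seed`` argument of the
driver functions).  The scalar full-conditional samplers are factored out so
that the Python-level API (``families.conditional_scale_draw``, the test
oracles) exercises exactly the code the sweep runs.

Family codes: 0 normal, 1 t, 2 slash, 3 contaminated normal, 4 laplace.

Parameter conventions (matching the model): Gamma(a, b) is shape-rate;
``tau_eps`` is the per-gene error precision; the latent scale factor u has
full conditional  u^{1/2} exp(-u tau e^2 / 2) g(u; nu).
"""

import math

import numpy as np
from numba import njit

GAMMA_PRIOR_SHAPE = 1.0
GAMMA_PRIOR_RATE = 0.005
T_DF_MAX = 100.0


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# scalar samplers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trunc_gamma01(a, b):
    """Exact draw from the kernel x^{a-1} e^{-bx} restricted to (0, 1).

    Three exact rejection branches keep the acceptance rate uniformly
    bounded away from 0 over (a, b):

    * b >= a-1 (and not tiny): Gamma(a, b) proposal, accept x < 1
      (acceptance ~ Phi((b-a)/sqrt(a)) >= ~0.3 on this branch);
    * small b or a <= 1: Beta(a, 1) proposal, accept with prob e^{-bx};
    * otherwise (increasing kernel, mass near 1): truncated-exponential
      proposal ~ e^{s x} on (0,1) with s = a-1-b, acceptance
      exp((a-1)(log x + 1 - x)) <= 1, the exact envelope ratio.
    """
    if b <= 1e-12:
        x = np.random.random_sample() ** (1.0 / a)
        return max(x, 1e-300)
    if b >= a - 1.0 and b >= 0.3:
        while True:
            x = np.random.gamma(a, 1.0 / b)
            if x < 1.0:
                return max(x, 1e-300)
    if a <= 1.0 or b <= 0.3:
        while True:
            x = np.random.random_sample() ** (1.0 / a)
            x = max(x, 1e-300)
            if math.log(np.random.random_sample() + 1e-300) < -b * x:
                return x
    s = a - 1.0 - b  # > 0 here
    c = 1.0 - math.exp(-s)
    while True:
        w = -math.log(1.0 - np.random.random_sample() * c) / s
        x = 1.0 - w
        if x <= 0.0:
            x = 1e-300
        if math.log(np.random.random_sample() + 1e-300) < \
                (a - 1.0) * (math.log(x) + w):
            return x


@njit(cache=True)
def _draw_invgauss(m, lam):
    """Inverse-Gaussian(mean m, shape lam) via Michael-Schucany-Haas."""
    zz = np.random.standard_normal()
    yy = zz * zz
    x = m + m * m * yy / (2.0 * lam) \
        - (m / (2.0 * lam)) * math.sqrt(4.0 * m * lam * yy + m * m * yy * yy)
    if x <= 0.0:
        x = 1e-300
    if np.random.random_sample() <= m / (m + x):
        return x
    return m * m / x


@njit(cache=True)
def _cn_contam_prob(e2t, lam, gam):
    """P(u = gamma | e, tau) for the contaminated normal scale conditional."""
    d = math.log(lam) - math.log(1.0 - lam) + 0.5 * math.log(gam) \
        + 0.5 * e2t * (1.0 - gam)
    if d > 35.0:
        return 1.0
    if d < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-d))


@njit(cache=True)
def _scale_draw(code, e, tau, s1, s2):
    """One draw of the latent scale factor u from its full conditional."""
    e2t = tau * e * e
    if code == 1:  # t: Gamma((v+1)/2, (v + tau e^2)/2)
        return np.random.gamma((s1 + 1.0) * 0.5, 2.0 / (s1 + e2t))
    if code == 2:  # slash: Gamma(v + 1/2, tau e^2 / 2) truncated to (0,1)
        return _trunc_gamma01(s1 + 0.5, 0.5 * e2t)
    if code == 3:  # contaminated normal: two-point on {gamma, 1}
        if np.random.random_sample() < _cn_contam_prob(e2t, s1, s2):
            return s2
        return 1.0
    if code == 4:  # laplace: GIG(-1/2) == inverse Gaussian
        c = 0.5 * e2t
        if c < 1e-12:  # kernel collapses to inverse-gamma(1/2, v)
            g = max(np.random.gamma(0.5, 1.0), 1e-300)
            return s1 / g
        return _draw_invgauss(math.sqrt(s1 / c), 2.0 * s1)
    return 1.0


@njit(cache=True)
def _t_df_loglik(v, n, s_u, s_logu):
    """log p(u_1..u_n | v) for u ~ Gamma(v/2, v/2), up to a constant."""
    h = 0.5 * v
    return n * (h * math.log(h) - math.lgamma(h)) + (h - 1.0) * s_logu - h * s_u


@njit(cache=True)
def _t_df_step(v, n, s_u, s_logu, step, vmax):
    """One random-walk Metropolis step on log v (uniform(0, vmax) prior)."""
    lv = math.log(v)
    vp = math.exp(lv + step * np.random.standard_normal())
    if vp >= vmax:
        return v, 0
    lr = _t_df_loglik(vp, n, s_u, s_logu) - _t_df_loglik(v, n, s_u, s_logu) \
        + math.log(vp) - lv  # Jacobian of the log transform
    if math.log(np.random.random_sample() + 1e-300) < lr:
        return vp, 1
    return v, 0


# ---------------------------------------------------------------------------
# per-gene pattern + mean update (block means integrated out)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gene_pattern_means(su, sy, tau_e, tau_mu, logp,
                        pat_assign, pat_nblocks, pat_comp, mu_row):
    """Collapsed draw of the equality pattern, then the block means.

    su[g] = sum_r u_{gr}, sy[g] = sum_r u_{gr} y_{gr}.  For a block B with
    prior precision tau_B: data precision A = tau_e * sum_B su, data term
    C = tau_e * sum_B sy; marginal log-weight contribution is
    0.5 log(tau_B / (tau_B + A)) + C^2 / (2 (tau_B + A)); posterior mean
    C / (tau_B + A), precision tau_B + A.
    """
    P, k = pat_assign.shape
    lw = np.empty(P)
    for pp in range(P):
        w = logp[pp]
        for b in range(pat_nblocks[pp]):
            tb = tau_mu[pat_comp[pp, b]]
            A = 0.0
            C = 0.0
            for g in range(k):
                if pat_assign[pp, g] == b:
                    A += su[g]
                    C += sy[g]
            A *= tau_e
            C *= tau_e
            w += 0.5 * (math.log(tb) - math.log(tb + A)) + 0.5 * C * C / (tb + A)
        lw[pp] = w
    m = lw[0]
    for pp in range(1, P):
        if lw[pp] > m:
            m = lw[pp]
    tot = 0.0
    for pp in range(P):
        lw[pp] = math.exp(lw[pp] - m)
        tot += lw[pp]
    r = np.random.random_sample() * tot
    zz = P - 1
    acc = 0.0
    for pp in range(P):
        acc += lw[pp]
        if r <= acc:
            zz = pp
            break
    for b in range(pat_nblocks[zz]):
        tb = tau_mu[pat_comp[zz, b]]
        A = 0.0
        C = 0.0
        for g in range(k):
            if pat_assign[zz, g] == b:
                A += su[g]
                C += sy[g]
        A *= tau_e
        C *= tau_e
        prec = tb + A
        mval = C / prec + np.random.standard_normal() / math.sqrt(prec)
        for g in range(k):
            if pat_assign[zz, g] == b:
                mu_row[g] = mval
    return zz


# ---------------------------------------------------------------------------
# one full Gibbs sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def sweep(y, group_of, mu, z, uu, bb, tau_eps, nu, p, tau_mu,
          pat_assign, pat_nblocks, pat_comp, family, mh_step):
    """One in-place sweep: patterns/means -> scales -> precisions -> shapes -> p.

    Returns the number of accepted t-df Metropolis moves (0 otherwise).
    """
    N, n = y.shape
    P, k = pat_assign.shape
    n_acc = 0

    logp = np.empty(P)
    for pp in range(P):
        logp[pp] = math.log(max(p[pp], 1e-300))

    # -- 1. equality pattern and group means, per gene
    su = np.empty(k)
    sy = np.empty(k)
    for i in range(N):
        for g in range(k):
            su[g] = 0.0
            sy[g] = 0.0
        for j in range(n):
            g = group_of[j]
            su[g] += uu[i, j]
            sy[g] += uu[i, j] * y[i, j]
        z[i] = _gene_pattern_means(su, sy, tau_eps[i], tau_mu, logp,
                                   pat_assign, pat_nblocks, pat_comp, mu[i])

    # -- 2. latent scale factors
    if family == 1 or family == 2 or family == 4:
        for i in range(N):
            v = nu[i, 0]
            for j in range(n):
                e = y[i, j] - mu[i, group_of[j]]
                uu[i, j] = _scale_draw(family, e, tau_eps[i], v, 0.0)
    elif family == 3:
        for i in range(N):
            lam = nu[i, 0]
            gam = nu[i, 1]
            for j in range(n):
                e = y[i, j] - mu[i, group_of[j]]
                if np.random.random_sample() < _cn_contam_prob(tau_eps[i] * e * e, lam, gam):
                    bb[i, j] = 1
                    uu[i, j] = gam
                else:
                    bb[i, j] = 0
                    uu[i, j] = 1.0

    # -- 3. error precisions tau_eps
    for i in range(N):
        sse = 0.0
        for j in range(n):
            e = y[i, j] - mu[i, group_of[j]]
            sse += uu[i, j] * e * e
        tau_eps[i] = np.random.gamma(GAMMA_PRIOR_SHAPE + 0.5 * n,
                                     1.0 / (GAMMA_PRIOR_RATE + 0.5 * sse))

    # -- 4. mean-prior precisions tau_mu (one count per block occurrence)
    cnt = np.zeros(k + 1)
    ssq = np.zeros(k + 1)
    for i in range(N):
        zz = z[i]
        for b in range(pat_nblocks[zz]):
            c = pat_comp[zz, b]
            for g in range(k):
                if pat_assign[zz, g] == b:
                    cnt[c] += 1.0
                    ssq[c] += mu[i, g] * mu[i, g]
                    break
    for c in range(k + 1):
        tau_mu[c] = np.random.gamma(GAMMA_PRIOR_SHAPE + 0.5 * cnt[c],
                                    1.0 / (GAMMA_PRIOR_RATE + 0.5 * ssq[c]))

    # -- 5. family shape parameters
    if family == 1:  # t df: random-walk MH on log v
        for i in range(N):
            s_u = 0.0
            s_logu = 0.0
            for j in range(n):
                s_u += uu[i, j]
                s_logu += math.log(max(uu[i, j], 1e-300))
            vnew, a = _t_df_step(nu[i, 0], n, s_u, s_logu, mh_step, T_DF_MAX)
            nu[i, 0] = vnew
            n_acc += a
    elif family == 2:  # slash exponent: conjugate gamma
        for i in range(N):
            s_logu = 0.0
            for j in range(n):
                s_logu += math.log(max(uu[i, j], 1e-300))
            nu[i, 0] = max(np.random.gamma(GAMMA_PRIOR_SHAPE + n,
                                           1.0 / (GAMMA_PRIOR_RATE - s_logu)), 1e-8)
    elif family == 4:  # laplace rate: conjugate gamma
        for i in range(N):
            s_inv = 0.0
            for j in range(n):
                s_inv += 1.0 / uu[i, j]
            nu[i, 0] = max(np.random.gamma(GAMMA_PRIOR_SHAPE + n,
                                           1.0 / (GAMMA_PRIOR_RATE + s_inv)), 1e-8)
    elif family == 3:  # contaminated normal (lambda, gamma)
        for i in range(N):
            m_i = 0.0
            r_i = 0.0
            for j in range(n):
                if bb[i, j] == 1:
                    e = y[i, j] - mu[i, group_of[j]]
                    m_i += 1.0
                    r_i += e * e
            lam = np.random.beta(1.0 + m_i, 1.0 + n - m_i)
            nu[i, 0] = min(max(lam, 1e-6), 1.0 - 1e-6)
            gam = _trunc_gamma01(0.5 * m_i + 1.0, 0.5 * tau_eps[i] * r_i)
            gam = min(max(gam, 1e-6), 1.0 - 1e-6)
            nu[i, 1] = gam
            for j in range(n):  # u is gamma^b: refresh after the gamma move
                uu[i, j] = gam if bb[i, j] == 1 else 1.0

    # -- 6. pattern mixing probabilities p ~ Dirichlet(1 + counts)
    cntp = np.zeros(P)
    for i in range(N):
        cntp[z[i]] += 1.0
    tot = 0.0
    for pp in range(P):
        g = np.random.gamma(1.0 + cntp[pp], 1.0)
        p[pp] = g
        tot += g
    for pp in range(P):
        p[pp] = max(p[pp] / tot, 1e-300)

    return n_acc


@njit(cache=True)
def run_chain(y, group_of, pat_assign, pat_nblocks, pat_comp, family,
              mu, z, uu, bb, tau_eps, nu, p, tau_mu,
              n_iter, n_burnin, thin, seed, mh_step,
              z_tr, p_tr, tmu_tr, te_tr, mu_tr, nu_tr):
    """Run one chain, storing retained draws into the preallocated arrays.

    Returns (status, n_accepted): status is -1 on success, else the first
    iteration at which a non-finite state component was detected.
    """
    np.random.seed(seed)
    N = y.shape[0]
    kept = 0
    n_acc = 0
    for it in range(n_iter):
        n_acc += sweep(y, group_of, mu, z, uu, bb, tau_eps, nu, p, tau_mu,
                       pat_assign, pat_nblocks, pat_comp, family, mh_step)
        if it % 250 == 0:
            chk = 0.0
            for i in range(N):
                chk += tau_eps[i] + mu[i, 0]
            if not math.isfinite(chk):
                return it, n_acc
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            for i in range(N):
                z_tr[kept, i] = z[i]
                te_tr[kept, i] = tau_eps[i]
                for g in range(mu.shape[1]):
                    mu_tr[kept, i, g] = mu[i, g]
                nu_tr[kept, i, 0] = nu[i, 0]
                nu_tr[kept, i, 1] = nu[i, 1]
            for pp in range(p.shape[0]):
                p_tr[kept, pp] = p[pp]
            for c in range(tau_mu.shape[0]):
                tmu_tr[kept, c] = tau_mu[c]
            kept += 1
    return -1, n_acc


# ---------------------------------------------------------------------------
# vectorised draw drivers (API and test oracles)
# ---------------------------------------------------------------------------

@njit(cache=True)
def scale_draws(code, e, tau, s1, s2, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _scale_draw(code, e, tau, s1, s2)
    return out


@njit(cache=True)
def gamma_draws(shape, rate, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.random.gamma(shape, 1.0 / rate)
    return out


@njit(cache=True)
def trunc_gamma01_draws(a, b, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _trunc_gamma01(a, b)
    return out


@njit(cache=True)
def pattern_mean_draws(su, sy, tau_e, tau_mu, p,
                       pat_assign, pat_nblocks, pat_comp, n, seed):
    """Repeated collapsed pattern+mean draws on one gene (for oracle tests)."""
    np.random.seed(seed)
    P, k = pat_assign.shape
    logp = np.empty(P)
    for pp in range(P):
        logp[pp] = math.log(max(p[pp], 1e-300))
    zs = np.empty(n, np.int64)
    mus = np.empty((n, k))
    mu_row = np.empty(k)
    for i in range(n):
        zs[i] = _gene_pattern_means(su, sy, tau_e, tau_mu, logp,
                                    pat_assign, pat_nblocks, pat_comp, mu_row)
        for g in range(k):
            mus[i, g] = mu_row[g]
    return zs, mus


@njit(cache=True)
def t_df_mh_chain(v0, n, s_u, s_logu, steps, step_size, seed):
    """Long-run MH chain for the t degrees of freedom at a fixed u-set."""
    np.random.seed(seed)
    out = np.empty(steps)
    v = v0
    for i in range(steps):
        v, _ = _t_df_step(v, n, s_u, s_logu, step_size, T_DF_MAX)
        out[i] = v
    return out
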