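"""Blocked Gibbs kernel for the nested-domain t-residual model.

The Student-t residual is represented as a scale mixture of normals: each
observation carries a latent precision multiplier lambda ~ Gamma(nu/2, nu/2),
which makes every location block (overarching means, domain and outcome
deviations, person and person-by-domain random intercepts/slopes)
conditionally Gaussian with closed-form updates.  The half-Cauchy hierarchy
SDs use the inverse-gamma auxiliary-variable representation
(tau^2 | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1/scale^2) gives tau ~ HalfCauchy(scale)),
so they are conjugate too.  Bounded SDs (uniform priors) and the degrees-of-
freedom parameter nu = 1/eta are updated by univariate slice sampling, which
is exact and tuning-free.

Everything here is numba-compiled; one call runs one chain and is
bit-reproducible for a fixed seed.
"""

import math

import numpy as np
from numba import njit

_TINY = 1e-10


@njit(cache=True)
def _logp_sd(s, m, ss):
    # conditional of an SD with flat (uniform) prior: prod N(x_j; 0, s^2)
    return -m * math.log(s) - ss / (2.0 * s * s)


@njit(cache=True)
def _slice_sd(x0, m, ss, lo, hi):
    """Slice-sample an SD on (lo, hi) with log-density -m*log(s) - ss/(2 s^2)."""
    height = _logp_sd(x0, m, ss) + math.log(np.random.random())
    L = lo
    R = hi
    x1 = x0
    for _ in range(200):
        x1 = L + (R - L) * np.random.random()
        if _logp_sd(x1, m, ss) >= height:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


@njit(cache=True)
def _logp_eta(eta, n_k, sl, slam):
    # likelihood of latent precisions lambda ~ Gamma(nu/2, nu/2), nu = 1/eta,
    # with flat prior on eta; sl = sum(log lambda), slam = sum(lambda)
    nu = 1.0 / eta
    h = 0.5 * nu
    return n_k * (h * math.log(h) - math.lgamma(h)) + h * (sl - slam)


@njit(cache=True)
def _slice_eta(x0, n_k, sl, slam, lo, hi):
    height = _logp_eta(x0, n_k, sl, slam) + math.log(np.random.random())
    L = lo
    R = hi
    x1 = x0
    for _ in range(200):
        x1 = L + (R - L) * np.random.random()
        if _logp_eta(x1, n_k, sl, slam) >= height:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


@njit(cache=True)
def gibbs_chain(
    y,
    sub,
    out,
    dom,
    pair,
    t,
    X,
    fam_nested,
    fam_prior_sd,
    S,
    D,
    K,
    use_u,
    use_w,
    use_v,
    use_z,
    fix_sigma,
    fix_nu,
    mu_prior_sd,
    cauchy_scale,
    sd_bound,
    eta_lo,
    eta_hi,
    n_warmup,
    n_kept,
    thin,
    seed,
    store,
):
    """Run one chain; fills ``store`` (n_kept x n_stored) with thinned draws.

    ``fix_sigma`` / ``fix_nu`` < 0 mean "free parameter".  Stored layout per
    family: nested -> [mu, delta_domain(D), delta_outcome(K), tau_domain,
    tau_outcome]; plain -> [beta(K)]; then one SD per enabled random-effect
    block (u, w, v, z order), then sigma(K) if free, then nu(K) if free.
    """
    np.random.seed(seed)
    N = y.shape[0]
    F = X.shape[1]
    SD_pairs = S * D

    mu = np.zeros(F)
    dD = np.zeros((F, D))
    dO = np.zeros((F, K))
    tauD = np.ones(F)
    tauO = np.ones(F)
    aD = np.ones(F)
    aO = np.ones(F)
    u = np.zeros(S)
    wre = np.zeros(S)
    v = np.zeros(SD_pairs)
    z = np.zeros(SD_pairs)
    sig_re = np.ones(4)
    sigma = np.ones(K)
    if fix_sigma > 0:
        for k in range(K):
            sigma[k] = fix_sigma
    eta = np.full(K, 0.1)
    nu = np.empty(K)
    for k in range(K):
        nu[k] = fix_nu if fix_nu > 0 else 1.0 / eta[k]
    lam = np.ones(N)
    wgt = np.empty(N)
    r = y.copy()

    counts = np.zeros(K)
    for n in range(N):
        counts[out[n]] += 1.0

    n_iter = n_warmup + n_kept * thin
    kept = 0
    for it in range(n_iter):
        # -- latent precision multipliers (t as scale mixture of normals)
        for n in range(N):
            k = out[n]
            rs = r[n] / sigma[k]
            rate = 0.5 * (nu[k] + rs * rs)
            lam[n] = np.random.gamma(0.5 * (nu[k] + 1.0), 1.0 / rate)
            wgt[n] = lam[n] / (sigma[k] * sigma[k])

        # -- effect families
        for f in range(F):
            if fam_nested[f]:
                # overarching mean
                A = 1.0 / (mu_prior_sd * mu_prior_sd)
                B = 0.0
                for n in range(N):
                    xv = X[n, f]
                    r[n] += xv * mu[f]
                    A += wgt[n] * xv * xv
                    B += wgt[n] * xv * r[n]
                mu[f] = np.random.normal(B / A, math.sqrt(1.0 / A))
                for n in range(N):
                    r[n] -= X[n, f] * mu[f]

                # domain deviations
                Ad = np.zeros(D)
                Bd = np.zeros(D)
                for n in range(N):
                    dd = dom[n]
                    xv = X[n, f]
                    r[n] += xv * dD[f, dd]
                    Ad[dd] += wgt[n] * xv * xv
                    Bd[dd] += wgt[n] * xv * r[n]
                prec0 = 1.0 / (tauD[f] * tauD[f])
                for dd in range(D):
                    Atot = prec0 + Ad[dd]
                    dD[f, dd] = np.random.normal(Bd[dd] / Atot, math.sqrt(1.0 / Atot))
                for n in range(N):
                    r[n] -= X[n, f] * dD[f, dom[n]]

                # outcome deviations
                Ak = np.zeros(K)
                Bk = np.zeros(K)
                for n in range(N):
                    kk = out[n]
                    xv = X[n, f]
                    r[n] += xv * dO[f, kk]
                    Ak[kk] += wgt[n] * xv * xv
                    Bk[kk] += wgt[n] * xv * r[n]
                prec0 = 1.0 / (tauO[f] * tauO[f])
                for kk in range(K):
                    Atot = prec0 + Ak[kk]
                    dO[f, kk] = np.random.normal(Bk[kk] / Atot, math.sqrt(1.0 / Atot))
                for n in range(N):
                    r[n] -= X[n, f] * dO[f, out[n]]

                # hierarchy SDs: half-Cauchy via inverse-gamma mixture
                ssD = 0.0
                for dd in range(D):
                    ssD += dD[f, dd] * dD[f, dd]
                tau2 = (0.5 * ssD + 1.0 / aD[f]) / np.random.gamma(0.5 * (D + 1.0), 1.0)
                tauD[f] = math.sqrt(tau2)
                aD[f] = (1.0 / (cauchy_scale * cauchy_scale) + 1.0 / tau2) / np.random.gamma(
                    1.0, 1.0
                )
                ssO = 0.0
                for kk in range(K):
                    ssO += dO[f, kk] * dO[f, kk]
                tau2 = (0.5 * ssO + 1.0 / aO[f]) / np.random.gamma(0.5 * (K + 1.0), 1.0)
                tauO[f] = math.sqrt(tau2)
                aO[f] = (1.0 / (cauchy_scale * cauchy_scale) + 1.0 / tau2) / np.random.gamma(
                    1.0, 1.0
                )
            else:
                # independent per-outcome effects, fixed diffuse prior
                Ak = np.zeros(K)
                Bk = np.zeros(K)
                for n in range(N):
                    kk = out[n]
                    xv = X[n, f]
                    r[n] += xv * dO[f, kk]
                    Ak[kk] += wgt[n] * xv * xv
                    Bk[kk] += wgt[n] * xv * r[n]
                prec0 = 1.0 / (fam_prior_sd[f] * fam_prior_sd[f])
                for kk in range(K):
                    Atot = prec0 + Ak[kk]
                    dO[f, kk] = np.random.normal(Bk[kk] / Atot, math.sqrt(1.0 / Atot))
                for n in range(N):
                    r[n] -= X[n, f] * dO[f, out[n]]

        # -- random effects
        if use_u:
            Au = np.zeros(S)
            Bu = np.zeros(S)
            for n in range(N):
                s_ = sub[n]
                r[n] += u[s_]
                Au[s_] += wgt[n]
                Bu[s_] += wgt[n] * r[n]
            prec0 = 1.0 / (sig_re[0] * sig_re[0])
            ss = 0.0
            for s_ in range(S):
                Atot = prec0 + Au[s_]
                u[s_] = np.random.normal(Bu[s_] / Atot, math.sqrt(1.0 / Atot))
                ss += u[s_] * u[s_]
            for n in range(N):
                r[n] -= u[sub[n]]
            sig_re[0] = _slice_sd(sig_re[0], float(S), ss, _TINY, sd_bound)

        if use_w:
            Au = np.zeros(S)
            Bu = np.zeros(S)
            for n in range(N):
                s_ = sub[n]
                tv = t[n]
                r[n] += wre[s_] * tv
                Au[s_] += wgt[n] * tv * tv
                Bu[s_] += wgt[n] * tv * r[n]
            prec0 = 1.0 / (sig_re[1] * sig_re[1])
            ss = 0.0
            for s_ in range(S):
                Atot = prec0 + Au[s_]
                wre[s_] = np.random.normal(Bu[s_] / Atot, math.sqrt(1.0 / Atot))
                ss += wre[s_] * wre[s_]
            for n in range(N):
                r[n] -= wre[sub[n]] * t[n]
            sig_re[1] = _slice_sd(sig_re[1], float(S), ss, _TINY, sd_bound)

        if use_v:
            Ap = np.zeros(SD_pairs)
            Bp = np.zeros(SD_pairs)
            for n in range(N):
                p_ = pair[n]
                r[n] += v[p_]
                Ap[p_] += wgt[n]
                Bp[p_] += wgt[n] * r[n]
            prec0 = 1.0 / (sig_re[2] * sig_re[2])
            ss = 0.0
            for p_ in range(SD_pairs):
                Atot = prec0 + Ap[p_]
                v[p_] = np.random.normal(Bp[p_] / Atot, math.sqrt(1.0 / Atot))
                ss += v[p_] * v[p_]
            for n in range(N):
                r[n] -= v[pair[n]]
            sig_re[2] = _slice_sd(sig_re[2], float(SD_pairs), ss, _TINY, sd_bound)

        if use_z:
            Ap = np.zeros(SD_pairs)
            Bp = np.zeros(SD_pairs)
            for n in range(N):
                p_ = pair[n]
                tv = t[n]
                r[n] += z[p_] * tv
                Ap[p_] += wgt[n] * tv * tv
                Bp[p_] += wgt[n] * tv * r[n]
            prec0 = 1.0 / (sig_re[3] * sig_re[3])
            ss = 0.0
            for p_ in range(SD_pairs):
                Atot = prec0 + Ap[p_]
                z[p_] = np.random.normal(Bp[p_] / Atot, math.sqrt(1.0 / Atot))
                ss += z[p_] * z[p_]
            for n in range(N):
                r[n] -= z[pair[n]] * t[n]
            sig_re[3] = _slice_sd(sig_re[3], float(SD_pairs), ss, _TINY, sd_bound)

        # -- residual scales
        if fix_sigma < 0:
            ssk = np.zeros(K)
            for n in range(N):
                ssk[out[n]] += lam[n] * r[n] * r[n]
            for k in range(K):
                sigma[k] = _slice_sd(sigma[k], counts[k], ssk[k], _TINY, sd_bound)

        # -- degrees of freedom via eta = 1/nu
        if fix_nu < 0:
            sl = np.zeros(K)
            slam = np.zeros(K)
            for n in range(N):
                k = out[n]
                sl[k] += math.log(lam[n])
                slam[k] += lam[n]
            for k in range(K):
                eta[k] = _slice_eta(eta[k], counts[k], sl[k], slam[k], eta_lo, eta_hi)
                nu[k] = 1.0 / eta[k]

        # -- store thinned post-warmup draws
        idx = it - n_warmup
        if idx >= 0 and idx % thin == thin - 1:
            pos = 0
            for f in range(F):
                if fam_nested[f]:
                    store[kept, pos] = mu[f]
                    pos += 1
                    for dd in range(D):
                        store[kept, pos] = dD[f, dd]
                        pos += 1
                    for kk in range(K):
                        store[kept, pos] = dO[f, kk]
                        pos += 1
                    store[kept, pos] = tauD[f]
                    store[kept, pos + 1] = tauO[f]
                    pos += 2
                else:
                    for kk in range(K):
                        store[kept, pos] = dO[f, kk]
                        pos += 1
            if use_u:
                store[kept, pos] = sig_re[0]
                pos += 1
            if use_w:
                store[kept, pos] = sig_re[1]
                pos += 1
            if use_v:
                store[kept, pos] = sig_re[2]
                pos += 1
            if use_z:
                store[kept, pos] = sig_re[3]
                pos += 1
            if fix_sigma < 0:
                for k in range(K):
                    store[kept, pos] = sigma[k]
                    pos += 1
            if fix_nu < 0:
                for k in range(K):
                    store[kept, pos] = nu[k]
                    pos += 1
            kept += 1
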