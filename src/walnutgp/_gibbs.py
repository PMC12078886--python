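"""Numba single-site Gibbs kernels for the Bayesian-alphabet samplers.

One kernel serves all five models, dispatched on an integer code:

====  ===========  ===========================================================
code  model        prior on marker effect u_j
====  ===========  ===========================================================
0     BRR          N(0, s2u) with a common scaled-inv-chi2 variance
1     BayesA       N(0, s2_j), per-marker scaled-inv-chi2 variances
2     BayesB       point mass at 0 w.p. pi + BayesA-type slab
3     BayesC       point mass at 0 w.p. pi + common-variance Gaussian slab
4     BL           N(0, s2e * tau2_j), tau2_j ~ Exp(lambda2/2) (Bayesian
                   LASSO: double-exponential marginal), lambda2 ~ Gamma
====  ===========  ===========================================================

Residuals are updated incrementally (rank-one) per marker sweep.  The
kernel seeds numpy's legacy global generator, so a fixed seed gives an
identical chain.
"""

import numpy as np
from numba import njit

MODEL_CODES = {"brr": 0, "bayes_a": 1, "bayes_b": 2, "bayes_c": 3, "bayes_lasso": 4}


@njit(cache=True)
def _rinvgauss(mu, lam):
    # Michael-Schucany-Haas transform
    v = np.random.standard_normal()
    y = v * v
    x = mu + mu * mu * y / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.uniform(0.0, 1.0) <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def gibbs_sample(Xc, y, W, model, n_iter, burn_in, df_u, S_u, df_e, S_e,
                 pi, update_pi, bl_shape, bl_rate, seed):
    """Run the sampler; return posterior means and the sigma2_e chain.

    Returns (u_mean, b_mean, s2e_chain, incl_prob, s2u_mean, pi_chain).
    """
    np.random.seed(seed)
    n, m = Xc.shape
    p = W.shape[1]

    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xc[i, j] * Xc[i, j]
        xtx[j] = s
    wtw = np.empty(p)
    for q in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, q] * W[i, q]
        wtw[q] = s

    u = np.zeros(m)
    b = np.zeros(p)
    delta = np.ones(m, dtype=np.int8)    # inclusion indicators (BayesB/C)
    var_j = np.full(m, S_u)              # per-marker variances (BayesA/B)
    s2u = S_u                            # common variance (BRR/BayesC)
    tau2 = np.ones(m)                    # BL local scales
    lambda2 = bl_shape / bl_rate if bl_rate > 0.0 else 1.0
    s2e = S_e if S_e > 0.0 else 1.0

    e = y.copy()
    for i in range(n):
        for q in range(p):
            e[i] -= W[i, q] * b[q]

    u_mean = np.zeros(m)
    b_mean = np.zeros(p)
    incl = np.zeros(m)
    s2e_chain = np.zeros(n_iter)
    pi_chain = np.zeros(n_iter)
    s2u_acc = 0.0
    n_keep = 0

    for it in range(n_iter):
        # --- fixed effects (flat prior) ---
        for q in range(p):
            if wtw[q] <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += W[i, q] * e[i]
            rhs += wtw[q] * b[q]
            mean = rhs / wtw[q]
            new = mean + np.sqrt(s2e / wtw[q]) * np.random.standard_normal()
            diff = new - b[q]
            for i in range(n):
                e[i] -= W[i, q] * diff
            b[q] = new

        # --- marker effects ---
        sum_u2_common = 0.0      # for BRR / BayesC common variance
        n_in = 0
        for j in range(m):
            c = xtx[j]
            if c <= 0.0:
                u[j] = 0.0
                continue
            # prior precision multiplier lam_r = s2e / prior_var
            if model == 0:
                lam_r = s2e / s2u
            elif model == 1 or model == 2:
                lam_r = s2e / var_j[j]
            elif model == 3:
                lam_r = s2e / s2u
            else:
                lam_r = 1.0 / tau2[j]

            if model == 2 or model == 3:
                # spike-and-slab: remove marker from residual, then decide
                old = u[j]
                if old != 0.0:
                    for i in range(n):
                        e[i] += Xc[i, j] * old
                rhs = 0.0
                for i in range(n):
                    rhs += Xc[i, j] * e[i]
                log_odds = (
                    np.log((1.0 - pi) / pi)
                    + 0.5 * np.log(lam_r / (c + lam_r))
                    + 0.5 * rhs * rhs / (s2e * (c + lam_r))
                )
                prob_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.uniform(0.0, 1.0) < prob_in:
                    delta[j] = 1
                    mean = rhs / (c + lam_r)
                    new = mean + np.sqrt(s2e / (c + lam_r)) * np.random.standard_normal()
                    for i in range(n):
                        e[i] -= Xc[i, j] * new
                    u[j] = new
                    n_in += 1
                    if model == 3:
                        sum_u2_common += new * new
                else:
                    delta[j] = 0
                    u[j] = 0.0
            else:
                old = u[j]
                rhs = c * old
                for i in range(n):
                    rhs += Xc[i, j] * e[i]
                mean = rhs / (c + lam_r)
                new = mean + np.sqrt(s2e / (c + lam_r)) * np.random.standard_normal()
                diff = new - old
                for i in range(n):
                    e[i] -= Xc[i, j] * diff
                u[j] = new
                if model == 0:
                    sum_u2_common += new * new

        # --- marker-variance updates ---
        if model == 0:
            s2u = (S_u * df_u + sum_u2_common) / np.random.chisquare(df_u + m)
        elif model == 1:
            for j in range(m):
                var_j[j] = (S_u * df_u + u[j] * u[j]) / np.random.chisquare(df_u + 1.0)
        elif model == 2:
            for j in range(m):
                if delta[j] == 1:
                    var_j[j] = (S_u * df_u + u[j] * u[j]) / np.random.chisquare(df_u + 1.0)
                else:
                    var_j[j] = S_u * df_u / np.random.chisquare(df_u)
        elif model == 3:
            s2u = (S_u * df_u + sum_u2_common) / np.random.chisquare(df_u + n_in)
        else:
            sum_tau2 = 0.0
            for j in range(m):
                uj2 = u[j] * u[j]
                if uj2 < 1e-12:
                    uj2 = 1e-12
                inv_tau2 = _rinvgauss(np.sqrt(lambda2 * s2e / uj2), lambda2)
                tau2[j] = 1.0 / inv_tau2
                sum_tau2 += tau2[j]
            lambda2 = np.random.gamma(bl_shape + m, 1.0 / (bl_rate + 0.5 * sum_tau2))

        if (model == 2 or model == 3) and update_pi:
            n_zero = m - n_in
            pi = np.random.beta(1.0 + n_zero, 1.0 + n_in)

        # --- residual variance ---
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + df_e * S_e) / np.random.chisquare(n + df_e)

        s2e_chain[it] = s2e
        pi_chain[it] = pi
        if it >= burn_in:
            n_keep += 1
            for j in range(m):
                u_mean[j] += u[j]
                incl[j] += delta[j] if (model == 2 or model == 3) else 1.0
            for q in range(p):
                b_mean[q] += b[q]
            if model == 0 or model == 3:
                s2u_acc += s2u
            elif model == 4:
                s2u_acc += s2e * 2.0 / lambda2   # marginal prior variance
            else:
                acc = 0.0
                for j in range(m):
                    acc += var_j[j]
                s2u_acc += acc / m

    inv = 1.0 / n_keep
    return (u_mean * inv, b_mean * inv, s2e_chain, incl * inv,
            s2u_acc * inv, pi_chain)


def split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a scalar chain."""
    x = np.asarray(chain, dtype=float)
    x = x[: (len(x) // 2) * 2]
    if len(x) < 8:
        return float("nan")
    halves = x.reshape(2, -1)
    n = halves.shape[1]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))
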