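"""Independent brute-force implementations used only as test oracles.

Everything here is deliberately written against the raw formulas with
generic optimizers / Monte Carlo, sharing no code path with the package
internals it checks.
"""

import numpy as np
from scipy import optimize
from scipy import stats as sps


def numeric_optimal_contrast(mu, n, A=None):
    """Maximize c'mu / sqrt(c'Ac) s.t. sum(c)=0, |c|=1 with SLSQP."""
    mu = np.asarray(mu, float)
    n = np.asarray(n, float)
    A = np.diag(1.0 / n) if A is None else np.asarray(A, float)

    def neg(c):
        return -(c @ mu) / np.sqrt(c @ A @ c)

    best = None
    rng = np.random.default_rng(0)
    for _ in range(8):
        c0 = rng.standard_normal(len(mu))
        c0 -= c0.mean()
        c0 /= np.linalg.norm(c0)
        res = optimize.minimize(
            neg, c0, method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda c: c.sum()},
                         {"type": "eq", "fun": lambda c: c @ c - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    c = best.x - best.x.mean()
    c /= np.linalg.norm(c)
    return c, (c @ mu) / np.sqrt(c @ A @ c)


def numeric_constrained_objective(mu, n, A=None):
    """Max of w'K mu / sqrt(w'KAK'w) over w >= 0 (generic optimizer).

    K maps dose weights to a placebo-anchored contrast.  Scale
    invariant, so w is box-constrained to [0, 1] with several starts.
    """
    mu = np.asarray(mu, float)
    n = np.asarray(n, float)
    k = len(mu) - 1
    A = np.diag(1.0 / n) if A is None else np.asarray(A, float)
    K = np.hstack([-np.ones((k, 1)), np.eye(k)])
    Kmu = K @ mu
    KAK = K @ A @ K.T

    def neg(w):
        q = w @ KAK @ w
        return -(w @ Kmu) / np.sqrt(q)

    # scale invariance: restrict to the simplex sum(w) = 1, w >= 0
    best = np.inf
    rng = np.random.default_rng(1)
    starts = [np.ones(k) / k] + [np.eye(k)[i] * 0.9 + 0.1 / k
                                 for i in range(k)]
    starts += [rng.dirichlet(np.ones(k)) for _ in range(10)]
    for w0 in starts:
        res = optimize.minimize(
            neg, w0, method="SLSQP", bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and np.isfinite(res.fun):
            best = min(best, res.fun)
    return -best


def mc_equicoordinate_prob(t, R, df, ndraw=1_000_000, seed=0):
    """Monte-Carlo P(max T_m <= t) for a central multivariate t."""
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(np.asarray(R, float))
    B = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((ndraw, len(w))) @ B.T
    s = np.sqrt(rng.chisquare(df, ndraw) / df)
    return float(np.all(Z / s[:, None] <= t, axis=1).mean())


def _oracle_maxt_pvalues(tstats, R, df, seed=123):
    """Adjusted p-values via scipy's mvt CDF with an independent setup."""
    R = np.asarray(R, float)
    eps = 1e-6
    Rj = (1 - eps) * R + eps * np.eye(len(R))
    d = np.sqrt(np.diag(Rj))
    Rj = Rj / np.outer(d, d)
    out = []
    for t in tstats:
        if len(R) == 1:
            out.append(float(sps.t.sf(t, df)))
            continue
        p = sps.multivariate_t.cdf(
            np.full(len(R), t), loc=np.zeros(len(R)), shape=Rj, df=df,
            maxpts=120_000, random_state=np.random.default_rng(seed),
        )
        out.append(float(1.0 - p))
    return np.array(out)


def oracle_contrast(mu, n, J, constrained):
    """Contrast over arms J (placebo first) from the raw formulas."""
    from itertools import combinations

    mu = np.asarray(mu, float)
    n = np.asarray(n, float)
    k = len(mu) - 1
    if constrained:
        # enumerate supports, unconstrained closed form per support
        best, bestc = -np.inf, None
        for r in range(1, len(J)):
            for S in combinations(J[1:], r):
                sub = [J[0], *S]
                musub = mu[list(sub)]
                nsub = n[list(sub)]
                c = nsub * (musub - (musub * nsub).sum() / nsub.sum())
                if np.linalg.norm(c) < 1e-12:
                    continue
                c = c / np.linalg.norm(c)
                if c @ musub < 0:
                    c = -c
                if np.any(c[1:] < -1e-12):
                    continue
                full = np.zeros(k + 1)
                full[sub] = c
                obj = (full @ mu) / np.sqrt((full**2 / n).sum())
                if obj > best:
                    best, bestc = obj, full
        return bestc
    muJ = mu[list(J)]
    nJ = n[list(J)]
    c = nJ * (muJ - (muJ * nJ).sum() / nJ.sum())
    if np.linalg.norm(c) < 1e-12:
        return None
    c = c / np.linalg.norm(c)
    if c @ muJ < 0:
        c = -c
    full = np.zeros(k + 1)
    full[list(J)] = c
    return full


def oracle_group_pvalue(means, s, n, df, mu_profiles, doses_in_group):
    """Min adjusted maxT p-value for one dose group (constrained)."""
    J = [0, *doses_in_group]
    C = []
    for mu in mu_profiles.values():
        c = oracle_contrast(mu, n, J, constrained=True)
        if c is not None:
            C.append(c)
    C = np.array(C)
    G = (C / n) @ C.T
    d = np.sqrt(np.diag(G))
    R = G / np.outer(d, d)
    keep = []
    for m in range(len(C)):
        if not any(R[m, j] > 1 - 1e-12 for j in keep):
            keep.append(m)
    Ck, Rk = C[keep], R[np.ix_(keep, keep)]
    t = (Ck @ means) / (s * np.sqrt((Ck**2 / n).sum(axis=1)))
    return float(_oracle_maxt_pvalues(t, Rk, df).min())


def brute_force_closed_report(data_by_arm, doses, n, mu_profiles, alpha,
                              constrained):
    """Full closed test recomputed from scratch.

    ``mu_profiles`` maps model label -> guessed mean profile.  Returns
    (intersection p-values dict, elementary rejection dict).
    """
    from itertools import combinations

    k = len(doses) - 1
    n = np.asarray(n, float)
    means = np.array([np.mean(g) for g in data_by_arm])
    N = sum(len(g) for g in data_by_arm)
    df = N - k - 1
    s2 = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in data_by_arm) / df
    s = np.sqrt(s2)

    def contrast_for(mu, J):
        return oracle_contrast(mu, n, J, constrained)

    inter_p = {}
    for r in range(k, 0, -1):
        for I in combinations(range(1, k + 1), r):
            J = [0, *I]
            C = []
            for mu in mu_profiles.values():
                c = contrast_for(np.asarray(mu, float), J)
                if c is not None:
                    C.append(c)
            C = np.array(C)
            G = (C / n) @ C.T
            d = np.sqrt(np.diag(G))
            R = G / np.outer(d, d)
            # collapse duplicated contrasts
            keep = []
            for m in range(len(C)):
                if not any(R[m, j] > 1 - 1e-12 for j in keep):
                    keep.append(m)
            Ck = C[keep]
            Rk = R[np.ix_(keep, keep)]
            t = (Ck @ means) / (s * np.sqrt((Ck**2 / n).sum(axis=1)))
            q = _oracle_maxt_pvalues(t, Rk, df)
            inter_p[I] = float(q.min())
    elem_reject = {}
    for i in range(1, k + 1):
        elem_reject[i] = all(
            inter_p[I] < alpha for I in inter_p if i in I
        )
    return inter_p, elem_reject
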