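"""Numba-compiled numerical kernels shared by the estimation modules.

Everything here operates on plain float64 arrays so that the hot loops
(the 100-point glasso penalty path, permutation re-estimation inside the
network comparison test, and the bootstrap machinery) run at native speed.
The public modules wrap these kernels with validation, dataclasses and
pandas I/O; tests exercise the wrappers, so the kernels are covered
through the same code path the pipeline uses.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Hard threshold below which a precision entry counts as an exact zero.
EDGE_EPS = 1e-10

# ---------------------------------------------------------------------------
# Scalar special functions
# ---------------------------------------------------------------------------


@njit(cache=True)
def ndtri(u):
    """Inverse standard-normal CDF.

    Rational approximation (Acklam) refined with one Halley step using
    erfc, giving near machine precision on (0, 1).
    """
    if u <= 0.0:
        return -np.inf
    if u >= 1.0:
        return np.inf
    # rational approximation in three regimes
    p_low = 0.02425
    if u < p_low:
        q = math.sqrt(-2.0 * math.log(u))
        x = (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
              + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif u <= 1.0 - p_low:
        q = u - 0.5
        r = q * q
        x = (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
              - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
            (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
                - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
              - 1.328068155288572e+01) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - u))
        x = -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                 - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
               + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    # one Halley refinement step
    e = 0.5 * math.erfc(-x / math.sqrt(2.0)) - u
    v = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - v / (1.0 + 0.5 * x * v)
    return x


# ---------------------------------------------------------------------------
# Ranks, skewness, nonparanormal transform
# ---------------------------------------------------------------------------


@njit(cache=True)
def average_ranks(x):
    """1-based ranks with ties sharing their average rank."""
    n = x.shape[0]
    order = np.argsort(x)
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


@njit(cache=True)
def skewness_g1(x):
    """Unadjusted Fisher-Pearson skewness g1 = m3 / m2^{3/2}.

    Returns NaN for (numerically) constant input.
    """
    n = x.shape[0]
    mean = 0.0
    for i in range(n):
        mean += x[i]
    mean /= n
    m2 = 0.0
    m3 = 0.0
    for i in range(n):
        d = x[i] - mean
        m2 += d * d
        m3 += d * d * d
    m2 /= n
    m3 /= n
    denom = m2 ** 1.5
    # m2 of a numerically constant column can underflow to 0
    if m2 <= 0.0 or denom <= 0.0:
        return np.nan
    return m3 / denom


@njit(cache=True)
def npn_transform(x):
    """Nonparanormal (rank-Gaussianizing) transform of one column.

    Phi^{-1} of the Winsorized empirical CDF with truncation constant
    delta_n = 1 / (4 n^{1/4} sqrt(pi log n)), standardized to mean 0 and
    unit sample variance.  Depends on ranks only, hence idempotent and
    invariant to strictly monotone transformations of the input.
    """
    n = x.shape[0]
    r = average_ranks(x)
    delta = 1.0 / (4.0 * n ** 0.25 * math.sqrt(math.pi * math.log(n)))
    z = np.empty(n, dtype=np.float64)
    for i in range(n):
        u = r[i] / n
        if u < delta:
            u = delta
        elif u > 1.0 - delta:
            u = 1.0 - delta
        z[i] = ndtri(u)
    mean = 0.0
    for i in range(n):
        mean += z[i]
    mean /= n
    var = 0.0
    for i in range(n):
        d = z[i] - mean
        var += d * d
    if var <= 0.0:
        return np.full(n, np.nan)
    sd = math.sqrt(var / (n - 1))
    for i in range(n):
        z[i] = (z[i] - mean) / sd
    return z


@njit(cache=True)
def preprocess_core(X, threshold):
    """Screen columns by |g1| skewness and Gaussianize the offenders.

    Columns with |skew| <= threshold are standardized (mean 0, sample SD 1);
    the rest go through the nonparanormal transform.  Returns the processed
    matrix, the transformed flags, and raw/post skewness per column.
    Constant columns yield NaN skew and a NaN output column; the Python
    wrapper turns that into an explicit error.
    """
    n, p = X.shape
    Z = np.empty((n, p), dtype=np.float64)
    flags = np.zeros(p, dtype=np.bool_)
    raw_skew = np.empty(p, dtype=np.float64)
    post_skew = np.empty(p, dtype=np.float64)
    for j in range(p):
        col = X[:, j].copy()
        sk = skewness_g1(col)
        raw_skew[j] = sk
        if np.isnan(sk):
            Z[:, j] = np.nan
            post_skew[j] = np.nan
            continue
        if abs(sk) > threshold:
            Z[:, j] = npn_transform(col)
            flags[j] = True
        else:
            mean = 0.0
            for i in range(n):
                mean += col[i]
            mean /= n
            var = 0.0
            for i in range(n):
                d = col[i] - mean
                var += d * d
            sd = math.sqrt(var / (n - 1))
            for i in range(n):
                Z[i, j] = (col[i] - mean) / sd
        post_skew[j] = skewness_g1(Z[:, j])
    return Z, flags, raw_skew, post_skew


@njit(cache=True)
def corr_from_standardized(Z):
    """Pearson correlation of columns already standardized to SD 1 (ddof=1)."""
    n, p = Z.shape
    C = (Z.T @ Z) / (n - 1.0)
    for i in range(p):
        C[i, i] = 1.0
        for j in range(i + 1, p):
            v = 0.5 * (C[i, j] + C[j, i])
            if v > 1.0:
                v = 1.0
            elif v < -1.0:
                v = -1.0
            C[i, j] = v
            C[j, i] = v
    return C


# ---------------------------------------------------------------------------
# Graphical lasso (blockwise coordinate descent, unpenalized diagonal)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lasso_cd(W, S, j, beta, c, lam, tol, max_iter):
    """Coordinate descent for the column-j lasso subproblem.

    Minimizes 0.5 beta' W11 beta - s12' beta + lam * ||beta||_1 over the
    off-j coordinates; beta has length p with beta[j] fixed at 0.  The
    residual cache c = W @ beta is maintained incrementally and returned
    up to date, so callers can read w12 = c directly.  Sweeps alternate
    between full passes and passes over the active (nonzero) set.
    """
    p = S.shape[0]
    # initialize the cache
    for k in range(p):
        s = 0.0
        for l in range(p):
            s += W[k, l] * beta[l]
        c[k] = s
    it = 0
    while it < max_iter:
        # full pass
        dmax = 0.0
        for k in range(p):
            if k == j:
                continue
            wkk = W[k, k]
            r = S[k, j] - c[k] + wkk * beta[k]
            if r > lam:
                new = (r - lam) / wkk
            elif r < -lam:
                new = (r + lam) / wkk
            else:
                new = 0.0
            d = new - beta[k]
            if d != 0.0:
                beta[k] = new
                for l in range(p):
                    c[l] += W[l, k] * d
                if abs(d) > dmax:
                    dmax = abs(d)
        it += 1
        if dmax < tol:
            return
        # active-set passes until stable, then re-verify with a full pass
        while it < max_iter:
            dmax = 0.0
            for k in range(p):
                if k == j or beta[k] == 0.0:
                    continue
                wkk = W[k, k]
                r = S[k, j] - c[k] + wkk * beta[k]
                if r > lam:
                    new = (r - lam) / wkk
                elif r < -lam:
                    new = (r + lam) / wkk
                else:
                    new = 0.0
                d = new - beta[k]
                if d != 0.0:
                    beta[k] = new
                    for l in range(p):
                        c[l] += W[l, k] * d
                    if abs(d) > dmax:
                        dmax = abs(d)
            it += 1
            if dmax < tol:
                break


@njit(cache=True)
def glasso_core(S, lam, W, Beta, tol, max_iter):
    """One glasso solve, warm-started from (W, Beta) which are updated in place.

    W is the working covariance estimate (diagonal pinned to diag(S): the
    diagonal is not penalized), Beta[:, j] the regression coefficients of
    column j.  Returns (Theta, n_sweeps, converged).
    """
    p = S.shape[0]
    inner_tol = tol * 0.1
    n_sweeps = 0
    converged = False
    c = np.empty(p, dtype=np.float64)
    beta = np.empty(p, dtype=np.float64)
    for sweep in range(max_iter):
        n_sweeps = sweep + 1
        dmax = 0.0
        for j in range(p):
            W[j, j] = S[j, j]
            for k in range(p):
                beta[k] = Beta[k, j]
            _lasso_cd(W, S, j, beta, c, lam, inner_tol, 200)
            for k in range(p):
                Beta[k, j] = beta[k]
                if k == j:
                    continue
                w = c[k]  # w12 = W11 @ beta, maintained by the solver
                d = abs(w - W[k, j])
                if d > dmax:
                    dmax = d
                W[k, j] = w
                W[j, k] = w
        if dmax < tol:
            converged = True
            break
    # recover the precision matrix from the final regressions
    Theta = np.zeros((p, p), dtype=np.float64)
    for j in range(p):
        denom = W[j, j]
        for k in range(p):
            denom -= W[k, j] * Beta[k, j]
        theta_jj = 1.0 / denom
        Theta[j, j] = theta_jj
        for k in range(p):
            if k != j:
                Theta[k, j] = -Beta[k, j] * theta_jj
    # symmetrize; keep exact zeros where both directions agree
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            if abs(v) < EDGE_EPS:
                v = 0.0
            Theta[i, j] = v
            Theta[j, i] = v
    return Theta, n_sweeps, converged


@njit(cache=True)
def chol_logdet(A):
    """(log det A, success) via an in-kernel Cholesky factorization."""
    p = A.shape[0]
    L = np.zeros((p, p), dtype=np.float64)
    ld = 0.0
    for i in range(p):
        s = A[i, i]
        for k in range(i):
            s -= L[i, k] * L[i, k]
        if s <= 0.0:
            return 0.0, False
        L[i, i] = math.sqrt(s)
        ld += math.log(L[i, i])
        for j in range(i + 1, p):
            t = A[j, i]
            for k in range(i):
                t -= L[j, k] * L[i, k]
            L[j, i] = t / L[i, i]
    return 2.0 * ld, True


@njit(cache=True)
def lambda_grid(C, n_lambdas, lam_min_ratio):
    """Log-spaced penalty grid from lambda_max (empty graph) downward."""
    p = C.shape[0]
    lam_max = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            a = abs(C[i, j])
            if a > lam_max:
                lam_max = a
    grid = np.empty(n_lambdas, dtype=np.float64)
    if lam_max <= 0.0:
        for i in range(n_lambdas):
            grid[i] = 0.0
        return grid
    lo = math.log(lam_max * lam_min_ratio)
    hi = math.log(lam_max)
    for i in range(n_lambdas):
        if n_lambdas == 1:
            grid[i] = lam_max
        else:
            grid[i] = math.exp(hi + (lo - hi) * i / (n_lambdas - 1))
    return grid


@njit(cache=True)
def ebic_path_core(C, n, gamma, lambdas, tol, max_iter, thetas_out, store):
    """Glasso over a decreasing penalty grid with EBIC selection.

    Warm starts run down the grid.  EBIC uses the multivariate-normal
    profile log-likelihood ll = (n/2)(log det Theta - tr(C Theta)); the
    additive constant is irrelevant to selection.  Ties break toward the
    larger penalty (sparser model).  Returns (Theta_best, idx_best,
    edge_counts, logliks, ebics, ok).
    """
    p = C.shape[0]
    nlam = lambdas.shape[0]
    W = C.copy()
    Beta = np.zeros((p, p), dtype=np.float64)
    edge_counts = np.zeros(nlam, dtype=np.int64)
    logliks = np.empty(nlam, dtype=np.float64)
    ebics = np.empty(nlam, dtype=np.float64)
    best = np.inf
    best_idx = -1
    Theta_best = np.eye(p)
    ok = True
    for i in range(nlam):
        Theta, _, _ = glasso_core(C, lambdas[i], W, Beta, tol, max_iter)
        if store:
            thetas_out[i] = Theta
        E = 0
        for a in range(p):
            for b in range(a + 1, p):
                if abs(Theta[a, b]) > EDGE_EPS:
                    E += 1
        edge_counts[i] = E
        ld, spd = chol_logdet(Theta)
        if not spd:
            ok = False
            logliks[i] = np.nan
            ebics[i] = np.inf
            continue
        tr = 0.0
        for a in range(p):
            for b in range(p):
                tr += C[a, b] * Theta[b, a]
        ll = 0.5 * n * (ld - tr)
        logliks[i] = ll
        eb = -2.0 * ll + E * math.log(n) + 4.0 * E * gamma * math.log(p)
        ebics[i] = eb
        if eb < best:
            best = eb
            best_idx = i
            Theta_best = Theta.copy()
    if best_idx < 0:
        ok = False
    return Theta_best, best_idx, edge_counts, logliks, ebics, ok


@njit(cache=True)
def partial_from_precision(Theta):
    """Edge weights w_ij = -theta_ij / sqrt(theta_ii theta_jj), zero diagonal."""
    p = Theta.shape[0]
    W = np.zeros((p, p), dtype=np.float64)
    for i in range(p):
        for j in range(i + 1, p):
            w = -Theta[i, j] / math.sqrt(Theta[i, i] * Theta[j, j])
            W[i, j] = w
            W[j, i] = w
    return W


@njit(cache=True)
def edge_threshold_value(n, p):
    """Consistency threshold log(p(p-1)/2)/sqrt(n) on partial correlations.

    Penalized-likelihood EBIC selection admits spurious edges of tiny
    magnitude once the sample is large; zeroing weights below this bound
    (the rule behind qgraph's ``threshold`` option) removes them while
    leaving genuine edges intact.
    """
    return math.log(p * (p - 1) / 2.0) / math.sqrt(n)


@njit(cache=True)
def apply_edge_threshold(W, tau):
    p = W.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(W[i, j]) < tau:
                W[i, j] = 0.0
                W[j, i] = 0.0
    return W


@njit(cache=True)
def fit_weights_core(X, skew_threshold, gamma, n_lambdas, lam_min_ratio,
                     tol, max_iter, use_edge_threshold):
    """Full single-network pipeline: preprocess -> correlation -> EBIC-glasso.

    Returns (W, ok).  ok is False when a precision iterate lost positive
    definiteness (counted by callers as an estimation failure).
    """
    n = X.shape[0]
    p = X.shape[1]
    Z, _, _, _ = preprocess_core(X, skew_threshold)
    C = corr_from_standardized(Z)
    lambdas = lambda_grid(C, n_lambdas, lam_min_ratio)
    if lambdas[0] <= 0.0:
        return np.zeros((p, p), dtype=np.float64), True
    dummy = np.empty((0, p, p), dtype=np.float64)
    Theta, idx, _, _, _, ok = ebic_path_core(
        C, n, gamma, lambdas, tol, max_iter, dummy, False)
    if not ok:
        return np.zeros((p, p), dtype=np.float64), False
    W = partial_from_precision(Theta)
    if use_edge_threshold:
        apply_edge_threshold(W, edge_threshold_value(n, p))
    return W, True


# ---------------------------------------------------------------------------
# Permutation and bootstrap loops
# ---------------------------------------------------------------------------


@njit(cache=True)
def global_strength_core(W):
    p = W.shape[0]
    s = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            s += abs(W[i, j])
    return s


@njit(cache=True)
def nct_null_core(X_pooled, perms, n1, skew_threshold, gamma, n_lambdas,
                  lam_min_ratio, tol, max_iter, use_edge_threshold):
    """Re-estimate both group networks for every permutation.

    perms holds row indices of the pooled matrix; the first n1 entries of
    each row form permuted group 1.  Returns the null draws of the global
    strength difference S, the maximum edge difference M, the per-edge
    absolute differences (upper triangle, row-major), and a failure mask.
    """
    K = perms.shape[0]
    n = X_pooled.shape[0]
    p = X_pooled.shape[1]
    ne = p * (p - 1) // 2
    s_null = np.full(K, np.nan)
    m_null = np.full(K, np.nan)
    edge_null = np.full((K, ne), np.nan)
    failed = np.zeros(K, dtype=np.bool_)
    X1 = np.empty((n1, p), dtype=np.float64)
    X2 = np.empty((n - n1, p), dtype=np.float64)
    for k in range(K):
        for i in range(n1):
            X1[i] = X_pooled[perms[k, i]]
        for i in range(n - n1):
            X2[i] = X_pooled[perms[k, n1 + i]]
        W1, ok1 = fit_weights_core(X1, skew_threshold, gamma, n_lambdas,
                                   lam_min_ratio, tol, max_iter,
                                   use_edge_threshold)
        W2, ok2 = fit_weights_core(X2, skew_threshold, gamma, n_lambdas,
                                   lam_min_ratio, tol, max_iter,
                                   use_edge_threshold)
        if not (ok1 and ok2):
            failed[k] = True
            continue
        s_null[k] = abs(global_strength_core(W1) - global_strength_core(W2))
        m = 0.0
        e = 0
        for i in range(p):
            for j in range(i + 1, p):
                d = abs(W1[i, j] - W2[i, j])
                edge_null[k, e] = d
                e += 1
                if d > m:
                    m = d
        m_null[k] = m
    return s_null, m_null, edge_null, failed


@njit(cache=True)
def subsample_weights_core(X, idx_mat, skew_threshold, gamma, n_lambdas,
                           lam_min_ratio, tol, max_iter, use_edge_threshold):
    """Estimate one network per row of subsample/bootstrap indices."""
    B = idx_mat.shape[0]
    m = idx_mat.shape[1]
    p = X.shape[1]
    W_stack = np.full((B, p, p), np.nan)
    failed = np.zeros(B, dtype=np.bool_)
    Xb = np.empty((m, p), dtype=np.float64)
    for b in range(B):
        for i in range(m):
            Xb[i] = X[idx_mat[b, i]]
        W, ok = fit_weights_core(Xb, skew_threshold, gamma, n_lambdas,
                                 lam_min_ratio, tol, max_iter,
                                 use_edge_threshold)
        if not ok:
            failed[b] = True
            continue
        W_stack[b] = W
    return W_stack, failed
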