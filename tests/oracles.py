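"""Independent reference solvers used only to cross-check the package.

The ADMM solver below attacks the same penalized log-det objective as the
package's coordinate-descent glasso but through a completely different
algorithm (eigendecomposition-based proximal steps), so agreement between
the two is a meaningful correctness check rather than a tautology.
"""

import numpy as np


def glasso_admm(S, lam, rho=1.0, max_iter=5000, tol=1e-10):
    """ADMM for min_Theta -logdet(Theta) + tr(S Theta) + lam*||Theta||_1,off.

    Returns the precision matrix estimate.  The diagonal is unpenalized,
    matching the package's convention.
    """
    p = S.shape[0]
    Theta = np.eye(p)
    Z = np.eye(p)
    U = np.zeros((p, p))
    penalty = lam * (1.0 - np.eye(p))
    for _ in range(max_iter):
        # Theta-update: minimize -logdet + tr(S Theta) + rho/2 ||Theta-Z+U||^2
        vals, vecs = np.linalg.eigh(rho * (Z - U) - S)
        theta_vals = (vals + np.sqrt(vals ** 2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (vecs * theta_vals) @ vecs.T
        # Z-update: soft-threshold off-diagonal
        A = Theta + U
        Z_new = np.sign(A) * np.maximum(np.abs(A) - penalty / rho, 0.0)
        np.fill_diagonal(Z_new, np.diag(A))
        # dual update
        U = U + Theta - Z_new
        r_norm = np.linalg.norm(Theta - Z_new)
        s_norm = np.linalg.norm(rho * (Z_new - Z))
        Z = Z_new
        if r_norm < tol and s_norm < tol:
            break
    return 0.5 * (Z + Z.T)


def skewness_bruteforce(x):
    """Direct evaluation of g1 = m3 / m2^{3/2} from its definition."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    return m3 / m2 ** 1.5
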