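"""Independent brute-force oracles.

These deliberately avoid the package's vectorised code paths: plain
Python loops and direct formulas, used to freeze expected values in the
tests.  Keep them slow and obvious.
"""
import numpy as np


def finite_difference_hessian(energy, coords, eps=1e-4):
    """Central-difference Hessian of ``energy`` (a function of an (N, 3)
    configuration) at ``coords``; returns a (3N, 3N) array."""
    x0 = np.asarray(coords, dtype=float).ravel()
    dim = x0.size
    h = np.zeros((dim, dim))
    for p in range(dim):
        for q in range(p, dim):
            val = 0.0
            for sp in (1, -1):
                for sq in (1, -1):
                    x = x0.copy()
                    x[p] += sp * eps
                    x[q] += sq * eps
                    val += sp * sq * energy(x.reshape(-1, 3))
            h[p, q] = h[q, p] = val / (4 * eps**2)
    return h


def fluctuation_profile(eigenvalues, cart_displacements, n_atoms):
    """Loop version of the 1/lambda-weighted squared displacement sum."""
    raw = np.zeros(n_atoms)
    for m, lam in enumerate(eigenvalues):
        d = cart_displacements[:, m].reshape(n_atoms, 3)
        for i in range(n_atoms):
            raw[i] += (d[i] @ d[i]) / lam
    return raw / raw.sum()


def correlation_from_covariance(eigenvalues, cart_displacements, n_atoms):
    """C_ij from the full 3N x 3N covariance sum (1/lambda) d d^T,
    contracting each 3x3 block's trace and normalising by the diagonal."""
    dim = 3 * n_atoms
    cov = np.zeros((dim, dim))
    for m, lam in enumerate(eigenvalues):
        d = cart_displacements[:, m]
        cov += np.outer(d, d) / lam
    g = np.zeros((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(n_atoms):
            g[i, j] = np.trace(cov[3 * i : 3 * i + 3, 3 * j : 3 * j + 3])
    d = np.sqrt(np.diag(g))
    return g / np.outer(d, d)


def squared_overlaps(cart_displacements, delta):
    """Per-mode normalised squared projections, one loop per mode."""
    out = []
    for m in range(cart_displacements.shape[1]):
        d = cart_displacements[:, m]
        out.append(
            (d @ delta) ** 2 / ((d @ d) * (delta @ delta))
        )
    return np.array(out)


def rmsip_double_sum(x, y, n=10):
    """Literal double sum over the n lowest modes of unit vectors."""
    total = 0.0
    for i in range(n):
        xi = x[:, i] / np.linalg.norm(x[:, i])
        for j in range(n):
            yj = y[:, j] / np.linalg.norm(y[:, j])
            total += (xi @ yj) ** 2
    return np.sqrt(total / n)


def bhattacharyya_direct(
    eigvals_a, disp_a, eigvals_b, disp_b, var_protein=0.95, var_joint=0.75
):
    """BC evaluated with plain determinants: build both covariances mode
    by mode, apply the two rank reductions, evaluate |.| directly."""

    def covariance(eigvals, disp, at_least):
        weights = 1.0 / np.asarray(eigvals)
        target = var_protein * weights.sum()
        cov = np.zeros((disp.shape[0], disp.shape[0]))
        acc = 0.0
        used = 0
        for m, w in enumerate(weights):
            cov += w * np.outer(disp[:, m], disp[:, m])
            acc += w
            used += 1
            if acc >= target - 1e-12 and used >= at_least:
                break
        return cov / np.trace(cov), used

    # the projection rank s may not exceed the covariance ranks, so the
    # per-protein mode counts are floored at s and recomputed
    at_least = 1
    while True:
        a, n_used = covariance(eigvals_a, disp_a, at_least)
        b, m_used = covariance(eigvals_b, disp_b, at_least)
        avg = (a + b) / 2
        eigvals, eigvecs = np.linalg.eigh(avg)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        acc, s = 0.0, 0
        target = var_joint * eigvals.sum()
        for lam in eigvals:
            acc += lam
            s += 1
            if acc >= target - 1e-12:
                break
        max_avail = min(len(eigvals_a), len(eigvals_b))
        if s <= min(n_used, m_used) or at_least >= max_avail:
            break
        at_least = min(s, max_avail)
    v = eigvecs[:, :s]
    a_t = v.T @ a @ v
    b_t = v.T @ b @ v
    ratio = np.linalg.det((a_t + b_t) / 2) / np.sqrt(
        np.linalg.det(a_t) * np.linalg.det(b_t)
    )
    return np.exp(-np.log(ratio) / (2 * s))
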