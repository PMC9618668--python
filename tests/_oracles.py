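"""Independent oracles used by the test suite.

These never call the package's samplers: posterior means for tiny single-stock
instances come from exact marginalization of the baseline frequencies and the
latent source allocations (analytic Dirichlet-multinomial integrals over every
allocation matrix) combined with brute-force quadrature over the rookery
destination parameters; density values come from an arbitrary-precision
re-implementation of the model's joint density in mpmath.
"""

from __future__ import annotations

import itertools

import mpmath as mp
import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import beta as beta_dist


def compositions(n: int, k: int):
    """All length-k tuples of nonnegative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in compositions(n - first, k - 1):
            yield (first,) + rest


def theta_posterior_mean_single_stock(
    X: np.ndarray,
    Y: np.ndarray,
    N: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    grid: int = 200,
) -> np.ndarray:
    """Exact-up-to-quadrature posterior mean of theta for M = 1.

    For one mixed stock the only non-conjugate parameters are the R rookery
    destination fractions phi_r1 (each marginally Beta(alpha_r1, alpha_r2)
    under the prior).  Conditional on theta(phi), the mixed-stock likelihood
    marginalized over baseline frequencies f and latent allocations is the
    polynomial

        p(Y | theta) = sum_n c_n prod_r theta_r^{n_r}

    where the sum runs over latent source-count vectors n and each coefficient
    c_n aggregates, over all allocation matrices `a` with column sums Y and
    row sums n, the multinomial coefficient times the Dirichlet-multinomial
    integral ratio B(beta + X_r + a_r) / B(beta + X_r) per rookery.  The
    remaining R-dimensional integral over phi is done by midpoint quadrature
    in the prior quantiles (exactly weights the Beta priors, including their
    boundary singularities).
    """
    X = np.asarray(X, dtype=np.int64)
    Y = np.asarray(Y, dtype=np.int64)
    N = np.asarray(N, dtype=float)
    R, H = X.shape
    assert Y.shape == (H,)
    assert alpha.shape == (R, 2)

    # every allocation matrix: cartesian product of per-haplotype compositions
    per_col = [np.array(list(compositions(int(Y[h]), R)), dtype=np.int64) for h in range(H)]
    K = int(np.prod([len(c) for c in per_col]))
    alloc = np.empty((K, R, H), dtype=np.int64)
    combos = itertools.product(*[range(len(c)) for c in per_col])
    for k, combo in enumerate(combos):
        for h, idx in enumerate(combo):
            alloc[k, :, h] = per_col[h][idx]

    beta_row = np.broadcast_to(np.asarray(beta, dtype=float), (H,))
    # log multinomial coefficients per column, summed
    log_coef = (
        gammaln(Y + 1.0)[None, :].sum(axis=1)
        - gammaln(alloc + 1.0).sum(axis=(1, 2))
    )
    # Dirichlet-multinomial integral per rookery row
    post = beta_row[None, None, :] + X[None, :, :] + alloc  # (K, R, H)
    base = beta_row[None, :] + X  # (R, H)
    log_B_post = gammaln(post).sum(axis=2) - gammaln(post.sum(axis=2))
    log_B_base = gammaln(base).sum(axis=1) - gammaln(base.sum(axis=1))
    log_w = log_coef + (log_B_post - log_B_base[None, :]).sum(axis=1)

    # aggregate allocation weights by their row-sum vector n
    n_vec = alloc.sum(axis=2)  # (K, R)
    uniq, inverse = np.unique(n_vec, axis=0, return_inverse=True)
    log_c = np.full(len(uniq), -np.inf)
    for g in range(len(uniq)):
        log_c[g] = logsumexp(log_w[inverse == g])

    # prior-quantile midpoint grid over phi_r1
    qs = (np.arange(grid) + 0.5) / grid
    axes = [beta_dist.ppf(qs, alpha[r, 0], alpha[r, 1]) for r in range(R)]
    mesh = np.meshgrid(*axes, indexing="ij")
    phi1 = np.stack([m.reshape(-1) for m in mesh], axis=1)  # (G, R)
    W = N[None, :] * phi1
    theta = W / W.sum(axis=1, keepdims=True)

    log_theta = np.log(np.clip(theta, 1e-300, None))
    num = np.zeros(R)
    den = 0.0
    chunk = 20_000
    # two passes: first find the global max for stable exponentiation
    max_ll = -np.inf
    for s in range(0, theta.shape[0], chunk):
        ll = logsumexp(log_c[None, :] + log_theta[s:s + chunk] @ uniq.T.astype(float), axis=1)
        max_ll = max(max_ll, ll.max())
    for s in range(0, theta.shape[0], chunk):
        ll = logsumexp(log_c[None, :] + log_theta[s:s + chunk] @ uniq.T.astype(float), axis=1)
        w = np.exp(ll - max_ll)
        num += w @ theta[s:s + chunk]
        den += w.sum()
    return num / den


def log_posterior_mp(
    alpha, beta, X, Y, N, phi, f
) -> float:
    """Arbitrary-precision evaluation of the joint log density.

    Direct transcription of the model: Dirichlet priors on each phi row and
    each f row, multinomial baseline term, and the mixture term with
    theta[m, r] = N_r phi[r, m] / sum_r' N_r' phi[r', m].
    """
    mp.mp.dps = 50
    R, Mp1 = np.shape(phi)
    M = Mp1 - 1
    H = np.shape(f)[1]

    def log_dir(x, a):
        out = mp.loggamma(mp.mpf(float(np.sum(a))))
        for xi, ai in zip(x, a):
            out -= mp.loggamma(mp.mpf(float(ai)))
            out += (mp.mpf(float(ai)) - 1) * mp.log(mp.mpf(float(xi)))
        return out

    total = mp.mpf(0)
    for r in range(R):
        total += log_dir(phi[r], alpha[r])
        total += log_dir(f[r], [beta[h] for h in range(H)])
        for h in range(H):
            if X[r][h]:
                total += mp.mpf(int(X[r][h])) * mp.log(mp.mpf(float(f[r][h])))
    for m in range(M):
        denom = mp.fsum([mp.mpf(float(N[r])) * mp.mpf(float(phi[r][m])) for r in range(R)])
        for h in range(H):
            if Y[m][h]:
                mix = mp.fsum([
                    mp.mpf(float(N[r])) * mp.mpf(float(phi[r][m])) / denom * mp.mpf(float(f[r][h]))
                    for r in range(R)
                ])
                total += mp.mpf(int(Y[m][h])) * mp.log(mix)
    return float(total)


def brute_force_truncation_classes(records, window):
    """O(n^2) pairwise equivalence classes of truncated sequences."""
    start, stop = window
    names = [r.name for r in records]
    seqs = [r.core_sequence[start:stop] for r in records]
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if seqs[i] == seqs[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[str]] = {}
    for i in range(len(names)):
        groups.setdefault(find(i), []).append(names[i])
    return {min(g): sorted(g) for g in groups.values()}
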