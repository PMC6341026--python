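"""Independent oracles used by the test-suite and the acceptance report.

Everything here deliberately avoids the package's own computational paths:
the quadrature oracle integrates the posterior numerically with its own
optimizer (scipy BFGS) and tensor Gauss-Hermite nodes; the inversion
sampler draws from an intensity via numeric CDF inversion; the projection
oracle recomputes mapped coordinates with a plain double loop.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import cholesky, solve
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp


# ---------------------------------------------------------------- quadrature
def gh_log_marginal(counts, exposure, Q, mean0, nodes: int = 10) -> float:
    """Tensor-product Gauss-Hermite estimate of log p(counts).

    p(counts) = integral of exp(loglik(z)) * N(z; 0, Q^-1) dz, evaluated
    with nodes placed adaptively around the posterior mode (found by BFGS,
    not by the package's Newton solver).  Exact as nodes -> infinity.
    """
    counts = np.asarray(counts, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    Q = np.asarray(Q, dtype=float)
    B = counts.size

    cholQ = cholesky(Q, lower=True)
    log_det_Q = 2.0 * np.sum(np.log(np.diag(cholQ)))

    def loglik(z):
        eta = mean0 + z
        mu = exposure * np.exp(eta)
        return (
            np.sum(counts * (np.log(exposure) + eta))
            - mu.sum()
            - gammaln(counts + 1).sum()
        )

    def log_prior(z):
        return 0.5 * log_det_Q - 0.5 * B * np.log(2 * np.pi) - 0.5 * z @ Q @ z

    def neg_log_post(z):
        return -(loglik(z) + log_prior(z))

    res = minimize(neg_log_post, np.zeros(B), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    mode = res.x
    hess = Q + np.diag(exposure * np.exp(mean0 + mode))  # analytic curvature
    cov = np.linalg.inv(hess)
    A = cholesky(cov, lower=True)
    log_det_A = float(np.sum(np.log(np.diag(A))))

    x, w = np.polynomial.hermite.hermgauss(nodes)
    grids = np.meshgrid(*([x] * B), indexing="ij")
    X = np.stack([g.ravel() for g in grids], axis=1)          # (nodes^B, B)
    logw = np.log(w)
    LW = sum(np.meshgrid(*([logw] * B), indexing="ij")).ravel()

    Z = mode + np.sqrt(2.0) * (X @ A.T)
    eta = mean0 + Z
    mu = exposure * np.exp(eta)
    loglik_all = (
        (Z + mean0) @ counts
        + counts @ np.log(exposure)
        - mu.sum(axis=1)
        - gammaln(counts + 1).sum()
    )
    log_prior_all = (
        0.5 * log_det_Q
        - 0.5 * B * np.log(2 * np.pi)
        - 0.5 * np.einsum("ij,jk,ik->i", Z, Q, Z)
    )
    integrand = loglik_all + log_prior_all + np.sum(X**2, axis=1) + LW
    return float(logsumexp(integrand) + 0.5 * B * np.log(2.0) + log_det_A)


# ----------------------------------------------------------------- sampling
def inversion_sample(intensity, L: float, rng: np.random.Generator,
                     grid_n: int = 20001) -> np.ndarray:
    """Draw an inhomogeneous-Poisson pattern via numeric CDF inversion."""
    s = np.linspace(0.0, L, grid_n)
    lam = np.asarray(intensity(s), dtype=float)
    cdf = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2 * np.diff(s))])
    total = cdf[-1]
    if total <= 0:
        return np.empty(0)
    n = rng.poisson(total)
    u = rng.uniform(0.0, total, size=n)
    return np.sort(np.interp(u, cdf, s))


def intensity_cdf(intensity, L: float, grid_n: int = 20001):
    """Normalised CDF of an intensity, as a callable for KS testing."""
    s = np.linspace(0.0, L, grid_n)
    lam = np.asarray(intensity(s), dtype=float)
    cdf = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2 * np.diff(s))])
    cdf /= cdf[-1]

    def F(x):
        return np.interp(x, s, cdf)

    return F


# ---------------------------------------------------------------- partitions
def set_partitions(items):
    """All set partitions of a sequence (recursive enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [smaller[k] | {first}] + smaller[k + 1:]
        yield smaller + [{first}]


def crp_log_prob(partition, m: float) -> float:
    """Chinese-restaurant-process log probability of a partition of N items:
    m^K * prod_c (|c|-1)! / prod_{t=1}^{N} (m + t - 1)."""
    N = sum(len(c) for c in partition)
    lp = len(partition) * np.log(m)
    for c in partition:
        lp += gammaln(len(c))
    lp -= np.sum(np.log(m + np.arange(N)))
    return float(lp)


def exact_partition_posterior(N: int, m: float, evidence) -> dict:
    """Enumerate all partitions of {0..N-1}; posterior weight of each is
    m^K * prod_c (|c|-1)! * exp(sum_c evidence(c)).  Returns a dict keyed
    by canonical assignment tuple with normalised probabilities."""
    out = {}
    logws = []
    keys = []
    for part in set_partitions(range(N)):
        logw = len(part) * np.log(m)
        for c in part:
            logw += gammaln(len(c)) + evidence(frozenset(c))
        keys.append(partition_key(part, N))
        logws.append(logw)
    logws = np.asarray(logws)
    probs = np.exp(logws - logsumexp(logws))
    for k, p in zip(keys, probs):
        out[k] = out.get(k, 0.0) + float(p)
    return out


def partition_key(partition, N: int) -> tuple:
    """Canonical assignment tuple (first-appearance labelling) of a
    partition given as an iterable of sets."""
    assign = [None] * N
    for cid, members in enumerate(partition):
        for i in members:
            assign[i] = cid
    seen, out = {}, []
    for a in assign:
        out.append(seen.setdefault(a, len(seen)))
    return tuple(out)


def assignment_key(assignment) -> tuple:
    seen, out = {}, []
    for a in assignment:
        out.append(seen.setdefault(int(a), len(seen)))
    return tuple(out)


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------- projection
def brute_force_project(centers, windows, L: float):
    """Reimplementation of the window-concatenation mapping as a plain
    double loop: windows is a list of (chrom, start, end) already in the
    concatenation order used by the package."""
    total = sum(e - s for _, s, e in windows)
    offsets = []
    run = 0
    for _, s, e in windows:
        offsets.append(run)
        run += e - s
    mapped = []
    for chrom, pos in centers:
        for (wc, ws, we), off in zip(windows, offsets):
            if wc == chrom and ws <= pos < we:
                mapped.append((off + pos - ws) * L / total)
                break
    return sorted(mapped)
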