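"""Dirichlet-process mixture sampling over partitions of point patterns.

Gibbs reassignment in the style of Neal's algorithm for non-conjugate
models, with the latent intensity of each cluster marginalised by the
Laplace-approximate evidence Lambda(.):

    P(i joins cluster c)  propto  n_c * exp[Lambda(c + i) - Lambda(c)]
    P(i opens a cluster)  propto  m   * exp[Lambda({i})]

so the stationary distribution over partitions is proportional to
m^K * prod_c (|c|-1)! * exp(sum_c Lambda(c)).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .lgcp import EvidenceCache, GridSpec, PriorSpec
from .projection import PointPattern

__all__ = [
    "ClusterState",
    "PosteriorSamples",
    "gibbs_sweep",
    "run_mcmc",
    "cobinding_matrix",
    "consensus_partition",
    "kmeans_baseline",
    "canonical_partition",
]

Evidence = Callable[[frozenset], float]


def canonical_partition(assignment: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by order of first appearance (0, 1, 2, ...)."""
    out = np.empty(len(assignment), dtype=np.int64)
    seen: dict[int, int] = {}
    for i, a in enumerate(assignment):
        out[i] = seen.setdefault(int(a), len(seen))
    return out


@dataclass
class ClusterState:
    """A partition of N items plus the DP precision m."""

    assignment: np.ndarray
    m: float = 1.0

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.m <= 0:
            raise ValueError("DP precision m must be positive")

    @property
    def N(self) -> int:
        return int(self.assignment.size)

    @property
    def clusters(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for i, a in enumerate(self.assignment):
            out.setdefault(int(a), set()).add(i)
        return out

    @property
    def K(self) -> int:
        return len(np.unique(self.assignment))

    def log_score(self, evidence: Evidence) -> float:
        """Unnormalised log joint: CRP weight + summed cluster evidence."""
        s = 0.0
        for members in self.clusters.values():
            s += np.log(self.m) + gammaln(len(members)) + evidence(frozenset(members))
        return float(s)


@dataclass
class PosteriorSamples:
    """Stored (canonicalised) partitions from an MCMC run."""

    partitions: list[np.ndarray]
    n_iter: int
    burn_in: int
    proteins: tuple[str, ...] = ()
    K_trace: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    log_score_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("require n_iter > burn_in >= 0")
        if not self.partitions:
            raise ValueError("no stored partitions")

    @property
    def N(self) -> int:
        return int(self.partitions[0].size)

    @property
    def cobinding(self) -> np.ndarray:
        return cobinding_matrix(self)


def gibbs_sweep(
    state: ClusterState,
    patterns: Sequence[PointPattern] | None = None,
    grid: GridSpec | None = None,
    theta: PriorSpec | None = None,
    rng: np.random.Generator | None = None,
    evidence: Evidence | None = None,
) -> ClusterState:
    """One full Gibbs sweep: reassign every item in index order.

    Either an ``evidence`` callable (frozenset of indices -> log marginal)
    or (patterns, grid, theta) must be supplied; building the cache here
    is supported but wasteful across sweeps.
    """
    if evidence is None:
        if patterns is None or grid is None:
            raise ValueError("supply either evidence or (patterns, grid)")
        evidence = EvidenceCache(patterns, grid, theta or PriorSpec())
    rng = rng if rng is not None else np.random.default_rng()

    assignment = state.assignment.copy()
    clusters = {cid: set(mem) for cid, mem in state.clusters.items()}
    next_id = max(clusters) + 1 if clusters else 0

    for i in range(assignment.size):
        cid_old = int(assignment[i])
        clusters[cid_old].discard(i)
        if not clusters[cid_old]:
            del clusters[cid_old]

        cand_ids = list(clusters)
        logw = np.empty(len(cand_ids) + 1)
        for j, cid in enumerate(cand_ids):
            mem = frozenset(clusters[cid])
            logw[j] = (
                np.log(len(mem)) + evidence(mem | {i}) - evidence(mem)
            )
        logw[-1] = np.log(state.m) + evidence(frozenset({i}))
        if not np.all(np.isfinite(logw)):
            bad = cand_ids[int(np.argmax(~np.isfinite(logw)))] if np.any(
                ~np.isfinite(logw[:-1])
            ) else "new"
            raise ValueError(
                f"non-finite reassignment weight for item {i} vs cluster {bad}"
            )
        w = np.exp(logw - logw.max())
        choice = rng.choice(logw.size, p=w / w.sum())
        if choice == len(cand_ids):
            cid_new = next_id
            next_id += 1
            clusters[cid_new] = {i}
        else:
            cid_new = cand_ids[choice]
            clusters[cid_new].add(i)
        assignment[i] = cid_new

    return ClusterState(assignment=assignment, m=state.m)


def run_mcmc(
    patterns: Sequence[PointPattern],
    grid: GridSpec,
    theta: PriorSpec = PriorSpec(),
    m: float = 1.0,
    n_iter: int = 200,
    burn_in: int = 0,
    seed: int = 0,
    evidence: Evidence | None = None,
) -> PosteriorSamples:
    """Run the partition sampler from an all-singletons start.

    Deterministic given ``seed``; stores every post-burn-in partition in
    canonical labelling, plus per-iteration K and unnormalised log joint.
    """
    if n_iter <= burn_in or burn_in < 0:
        raise ValueError("require n_iter > burn_in >= 0")
    if evidence is None:
        evidence = EvidenceCache(patterns, grid, theta)
    rng = np.random.default_rng(seed)
    N = len(patterns)
    state = ClusterState(assignment=np.arange(N), m=m)

    kept: list[np.ndarray] = []
    K_trace = np.empty(n_iter, dtype=np.int64)
    score_trace = np.empty(n_iter)
    for it in range(n_iter):
        state = gibbs_sweep(state, rng=rng, evidence=evidence)
        K_trace[it] = state.K
        score_trace[it] = state.log_score(evidence)
        if it >= burn_in:
            kept.append(canonical_partition(state.assignment))

    return PosteriorSamples(
        partitions=kept,
        n_iter=n_iter,
        burn_in=burn_in,
        proteins=tuple(p.protein for p in patterns),
        K_trace=K_trace,
        log_score_trace=score_trace,
    )


def cobinding_matrix(samples: PosteriorSamples | Sequence[np.ndarray]) -> np.ndarray:
    """Fraction of stored partitions in which each pair is co-assigned.

    Symmetric with unit diagonal; entries in [0, 1].
    """
    partitions = samples.partitions if isinstance(samples, PosteriorSamples) else list(
        samples
    )
    if not partitions:
        raise ValueError("need at least one stored partition")
    acc = np.zeros((len(partitions[0]), len(partitions[0])))
    for part in partitions:
        part = np.asarray(part)
        acc += (part[:, None] == part[None, :]).astype(float)
    return acc / len(partitions)


def consensus_partition(samples: PosteriorSamples | Sequence[np.ndarray]) -> np.ndarray:
    """Dahl's least-squares consensus: the stored partition minimising
    sum_{i<j} (1[c_i = c_j] - cobinding_ij)^2, earliest iteration on ties."""
    partitions = samples.partitions if isinstance(samples, PosteriorSamples) else list(
        samples
    )
    cb = cobinding_matrix(partitions)
    iu = np.triu_indices(cb.shape[0], k=1)
    best, best_loss = None, np.inf
    for part in partitions:
        part = np.asarray(part)
        co = (part[:, None] == part[None, :]).astype(float)
        loss = float(np.sum((co[iu] - cb[iu]) ** 2))
        if loss < best_loss:  # strict < keeps the earliest on ties
            best, best_loss = part, loss
    return canonical_partition(best)


def kmeans_baseline(
    intensity_matrix: np.ndarray, k: int | str = "auto", seed: int = 0
) -> np.ndarray:
    """K-means on per-protein intensity curves; k="auto" maximises the
    silhouette over k in {2, ..., min(8, N-1)}."""
    X = np.asarray(intensity_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (N >= 2) x B intensity matrix")
    N = X.shape[0]
    if np.allclose(X, X[0]):
        warnings.warn("all intensity rows identical; returning one cluster")
        return np.zeros(N, dtype=np.int64)
    if k == "auto":
        best_k, best_sil = None, -np.inf
        for kk in range(2, min(8, N - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(X)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(X, labels)
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k if best_k is not None else 2
    labels = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit_predict(X)
    return canonical_partition(labels)
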