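"""Multi-run fastICA core: whitening, run pooling, stability clustering.

One stabilized decomposition at order ``M`` is obtained by running
symmetric pow3 fastICA ``K`` times from different random rotations on
the same PCA-whitened data, pooling the ``K·M`` resulting components,
clustering them by the dissimilarity ``1 - |r|`` (Pearson correlation of
their gene-space weight vectors), and summarizing each of the ``M``
clusters by a stability index and a representative member (centrotype).

The stability index of a cluster :math:`C_k` is

.. math::

    I_q(C_k) = \\frac{1}{|C_k|^2} \\sum_{i,j \\in C_k} |r_{ij}|
             - \\frac{1}{|C_k| \\sum_{l \\ne k} |C_l|}
               \\sum_{i \\in C_k} \\sum_{j \\notin C_k} |r_{ij}|,

i.e. average within-cluster minus average between-cluster absolute
correlation; :math:`I_q = 1` corresponds to perfect clustering (|r| = 1
inside every cluster, 0 across clusters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .expression import ExpressionMatrix

__all__ = [
    "Whitening",
    "RawComponentSet",
    "ComponentCluster",
    "CorrelationMatrix",
    "cap_order",
    "whiten_reduce",
    "run_multi_ica",
    "correlation_matrix",
    "cluster_components",
    "stability_index",
    "average_stability",
    "extract_centrotypes",
    "orient_component",
]

# fastICA defaults; convergent regimes finish well under 100 symmetric
# iterations, while oscillating (over-decomposed) runs do not converge at
# any budget — their run log entry, not a retry, is the useful signal.
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
DEFAULT_RETRY_BUDGET = 0


def cap_order(m_requested: int, n_samples: int) -> int:
    """Cap the decomposition order at 0.9 × the number of samples.

    Moderate dimension reduction improves fastICA convergence; the cap is
    ``floor(0.9 * n_samples)`` with a lower clamp at 2.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    cap = math.floor(0.9 * n_samples)
    return max(2, min(int(m_requested), cap))


@dataclass
class Whitening:
    """PCA-reduced, whitened view of an expression matrix.

    ``whitened`` has shape (n_genes, M) with identity sample covariance
    over the retained dimensions; a whitened-space weight vector ``w``
    maps back to gene space as ``whitened @ w``.
    """

    whitened: np.ndarray
    singular_values: np.ndarray
    explained_variance_fraction: float
    sample_means: np.ndarray
    order: int

    def to_gene_space(self, w: np.ndarray) -> np.ndarray:
        """Project whitened-space component weights back onto genes."""
        return self.whitened @ np.asarray(w, dtype=float)


def whiten_reduce(X: ExpressionMatrix | np.ndarray, M: int) -> Whitening:
    """Reduce the gene point cloud to M dimensions by PCA and whiten it.

    Genes are the observations and samples the variables: each sample
    column is mean-centred over genes and the top-M principal directions
    are rescaled to unit variance.  Returns the whitened representation
    together with the fraction of total variance the M retained
    dimensions explain.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n_genes, n_samples = values.shape
    # per-sample centring leaves every column orthogonal to the ones vector
    limit = min(n_genes - 1, n_samples)
    if not 2 <= M <= limit:
        raise ValueError(f"order M={M} outside [2, {limit}] for shape {values.shape}")
    means = values.mean(axis=0)
    centred = values - means
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("expression matrix has zero variance")
    if s[M - 1] <= s[0] * 1e-12:
        raise ValueError(f"M={M} exceeds the numerical rank of the data")
    evf = float(np.sum(s[:M] ** 2) / total)
    whitened = U[:, :M] * math.sqrt(n_genes - 1)
    return Whitening(
        whitened=whitened,
        singular_values=s,
        explained_variance_fraction=evf,
        sample_means=means,
        order=M,
    )


@dataclass
class RawComponentSet:
    """Pooled components from K fastICA runs at one order M.

    ``components`` holds the whitened-space weight vectors (K·M × M) and
    ``gene_projections`` their unit-norm gene-space counterparts
    (K·M × n_genes); ``run_index[i]`` records which run produced row i.
    """

    components: np.ndarray
    gene_projections: np.ndarray
    run_index: np.ndarray
    order: int
    runs: int
    seed: int | None
    converged: np.ndarray = field(default=None)
    n_iterations: np.ndarray = field(default=None)
    retries_used: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = self.order * self.runs
        if self.components.shape[0] != n or self.gene_projections.shape[0] != n:
            raise ValueError("expected exactly K*M pooled components")
        counts = np.bincount(self.run_index, minlength=self.runs)
        if not np.all(counts == self.order):
            raise ValueError("each run must contribute exactly M components")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _sym_decorrelation(W: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(W @ W.T)
    # eigh can return slightly negative eigenvalues for near-singular W
    s = np.clip(s, 1e-12 * float(s.max()), None)
    return (u / np.sqrt(s)) @ u.T @ W


def _fastica_pow3(
    Y: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Symmetric fastICA with the cube contrast on whitened data Y (n × M).

    Returns the unmixing rotation W (M × M, rows = components), the
    number of iterations used and a convergence flag.
    """
    n, M = Y.shape
    W = _sym_decorrelation(rng.normal(size=(M, M)))
    for it in range(1, max_iter + 1):
        proj = Y @ W.T
        W1 = _sym_decorrelation((proj**3).T @ Y / n - 3.0 * W)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W1, W)) - 1.0)))
        W = W1
        if lim < tol:
            return W, it, True
    return W, max_iter, False


def _run_rng(seed: int | None, run: int, attempt: int) -> np.random.Generator:
    # counter-based sub-seeding: reproducible and independent across
    # (run, retry-attempt) pairs under one master seed
    entropy = 0 if seed is None else int(seed)
    return np.random.default_rng(np.random.SeedSequence([entropy, run, attempt]))


def run_multi_ica(
    X: ExpressionMatrix | np.ndarray,
    M: int,
    K: int,
    seed: int | None = None,
    *,
    whitening: Whitening | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    retry_budget: int = DEFAULT_RETRY_BUDGET,
    strict: bool = False,
) -> RawComponentSet:
    """Run fastICA K times from seeded random rotations and pool components.

    Non-converged runs are retried with fresh sub-seeds up to
    ``retry_budget`` times; a run still unconverged afterwards is kept
    (its final estimate enters the pool) and flagged in ``converged``,
    unless ``strict`` is set, in which case a ``RuntimeError`` listing
    the failing runs is raised.
    """
    if K < 2:
        raise ValueError("need at least K=2 runs")
    if whitening is None:
        values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
        n_samples = values.shape[1]
        if M > cap_order(M, n_samples):
            raise ValueError(
                f"M={M} exceeds the 0.9*n_samples cap ({cap_order(M, n_samples)})"
            )
        whitening = whiten_reduce(values, M)
    Y = whitening.whitened
    comps = np.empty((K * M, M))
    conv = np.zeros(K, dtype=bool)
    iters = np.zeros(K, dtype=int)
    retries = np.zeros(K, dtype=int)
    for run in range(K):
        for attempt in range(retry_budget + 1):
            W, it, ok = _fastica_pow3(Y, _run_rng(seed, run, attempt), tol, max_iter)
            if ok:
                break
        conv[run] = ok
        iters[run] = it
        retries[run] = attempt
        comps[run * M : (run + 1) * M] = W
    if strict and not conv.all():
        bad = np.flatnonzero(~conv).tolist()
        raise RuntimeError(f"fastICA failed to converge for runs {bad} (M={M})")
    gene_proj = comps @ Y.T  # (K*M, n_genes)
    norms = np.linalg.norm(gene_proj, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm component in gene space")
    gene_proj = gene_proj / norms
    return RawComponentSet(
        components=comps,
        gene_projections=gene_proj,
        run_index=np.repeat(np.arange(K), M),
        order=M,
        runs=K,
        seed=seed,
        converged=conv,
        n_iterations=iters,
        retries_used=retries,
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between pooled component weight vectors."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v

    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.values)


def correlation_matrix(raw: RawComponentSet) -> CorrelationMatrix:
    """Pearson correlations between all pooled gene-space components."""
    G = raw.gene_projections
    sd = G.std(axis=1)
    scale = np.abs(G).max(axis=1)
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(scale, 1e-300))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"constant component (run {raw.run_index[i]}, "
            f"component {i % raw.order}): correlation undefined"
        )
    R = np.corrcoef(G)
    return CorrelationMatrix(R)


@dataclass
class ComponentCluster:
    """One cluster of matched components pooled across runs."""

    member_indices: np.ndarray
    stability: float | None = None
    centrotype_index: int | None = None

    def __len__(self) -> int:
        return len(self.member_indices)


def cluster_components(
    raw: RawComponentSet,
    corr: CorrelationMatrix | None = None,
    linkage: str = "average",
) -> list[ComponentCluster]:
    """Cut an agglomerative 1-|r| dendrogram into exactly M clusters.

    Components are compared in gene space.  Returns the clusters ordered
    by their smallest member index; they partition all K·M components.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if corr is None:
        corr = correlation_matrix(raw)
    M = raw.order
    if M == 1:
        return [ComponentCluster(np.arange(raw.n_components))]
    D = 1.0 - corr.absolute
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    labels = fcluster(Z, t=M, criterion="maxclust")
    n_found = len(np.unique(labels))
    if n_found != M:
        raise RuntimeError(f"dendrogram cut produced {n_found} clusters, wanted {M}")
    clusters = [
        ComponentCluster(np.flatnonzero(labels == lab)) for lab in np.unique(labels)
    ]
    clusters.sort(key=lambda c: int(c.member_indices[0]))
    return clusters


def stability_index(
    clusters: list[ComponentCluster],
    corr: CorrelationMatrix | np.ndarray,
) -> np.ndarray:
    """Per-cluster stability: mean within- minus mean between-cluster |r|.

    For a single-cluster partition the between-cluster term is defined
    as 0 (its normalizing denominator vanishes).  Results are written
    back onto the clusters and returned in cluster order.
    """
    R = corr.absolute if isinstance(corr, CorrelationMatrix) else np.abs(np.asarray(corr))
    n = R.shape[0]
    sizes = np.array([len(c) for c in clusters])
    if np.any(sizes == 0):
        raise ValueError("empty cluster")
    if sizes.sum() != n:
        raise ValueError("clusters must partition the component index set")
    out = np.empty(len(clusters))
    for k, cluster in enumerate(clusters):
        idx = cluster.member_indices
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        size = len(idx)
        intra = float(R[np.ix_(idx, idx)].sum()) / size**2
        n_out = n - size
        if n_out == 0:
            inter = 0.0
        else:
            others = np.flatnonzero(~mask)
            inter = float(R[np.ix_(idx, others)].sum()) / (size * n_out)
        out[k] = intra - inter
        cluster.stability = out[k]
    return out


def average_stability(stabilities, k="all") -> float:
    """Mean of the top-k stability indices; ``k="all"`` gives S(M)."""
    vals = np.asarray(stabilities, dtype=float)
    vals = np.sort(vals)[::-1]
    if k == "all":
        k = len(vals)
    k = int(k)
    if not 1 <= k <= len(vals):
        raise ValueError(f"k={k} outside [1, {len(vals)}]")
    return float(vals[:k].mean())


def orient_component(weights: np.ndarray, tail_sd: float = 3.0) -> np.ndarray:
    """Standardize a gene weight vector and point its heaviest tail up.

    The vector is standardized to zero mean and unit variance; the tail
    weights are the total absolute sums of standardized weights beyond
    ``+tail_sd`` and below ``-tail_sd``.  The sign is flipped if the
    negative tail is heavier; exact ties (including two empty tails)
    fall back to the sign of the skewness, and zero skewness leaves the
    vector unchanged.  Idempotent.
    """
    w = np.asarray(weights, dtype=float)
    sd = w.std()
    if sd == 0:
        raise ValueError("cannot orient a constant weight vector")
    z = (w - w.mean()) / sd
    pos = float(z[z > tail_sd].sum())
    neg = float(-z[z < -tail_sd].sum())
    if neg > pos:
        return -z
    if neg < pos:
        return z
    g = float(skew(z))
    return -z if g < 0 else z


def extract_centrotypes(
    clusters: list[ComponentCluster],
    raw: RawComponentSet,
    corr: CorrelationMatrix | None = None,
    data: np.ndarray | None = None,
    tail_sd: float = 3.0,
    representative: str = "centrotype",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Representative metagene per cluster, ordered by descending stability.

    The centrotype of a cluster is the member maximizing the sum of
    absolute correlations to its co-members (ties broken by the lowest
    member index).  With ``representative="mean"`` the cluster is
    summarized by the average of its members after sign-aligning each
    to the centrotype (robust to the sign indeterminacy of ICA).
    Metagenes are standardized and oriented.  If a centred genes ×
    samples matrix is supplied, mixing columns are recomputed by least
    squares so that ``data ≈ metagenes.T @ mixing.T``.

    Returns ``(metagenes, mixing)`` with metagenes (M × n_genes) and
    mixing (n_samples × M) or None.
    """
    if representative not in ("centrotype", "mean"):
        raise ValueError("representative must be 'centrotype' or 'mean'")
    if corr is None:
        corr = correlation_matrix(raw)
    R = corr.absolute
    for cluster in clusters:
        idx = cluster.member_indices
        scores = R[np.ix_(idx, idx)].sum(axis=1)
        cluster.centrotype_index = int(idx[int(np.argmax(scores))])
    if any(c.stability is None for c in clusters):
        stability_index(clusters, corr)
    order = sorted(
        range(len(clusters)),
        key=lambda k: (-clusters[k].stability, clusters[k].member_indices[0]),
    )
    rows = []
    for k in order:
        cluster = clusters[k]
        centro = raw.gene_projections[cluster.centrotype_index]
        if representative == "centrotype":
            vec = centro
        else:
            members = raw.gene_projections[cluster.member_indices]
            signs = np.sign(members @ centro)
            signs[signs == 0] = 1.0
            vec = (members * signs[:, None]).mean(axis=0)
        rows.append(orient_component(vec, tail_sd=tail_sd))
    metagenes = np.vstack(rows)
    mixing = None
    if data is not None:
        # data (genes × samples) centred per sample; X_c ≈ S^T A^T
        sol, *_ = np.linalg.lstsq(metagenes.T, np.asarray(data, float), rcond=None)
        mixing = sol.T
    return metagenes, mixing
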