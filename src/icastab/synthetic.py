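"""Synthetic expression data and fixtures with known ground truth.

The factor-data generator draws X = S_true^T A_true^T + noise: a
*dense part* of k strong co-regulated gene modules (sparse
super-gaussian metagenes with gaussian sample loadings) plus
i.i.d. gaussian measurement noise.  Optional extras emulate further
features of real transcriptomes: weak overlapping gene programs (a
"sparse part" of many near-degenerate directions) and planted
small-gene-set components (1–3 genes with outlier weights).

Auxiliary generators produce degenerate fixtures: perfect component
clusters (the analytic I_q = 1 case), labeled two-line point clouds
for the k-lines clustering, and driver-metagene weight vectors with a
deterministic tail structure for the small-gene-set detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ica import RawComponentSet

__all__ = [
    "GeneratorConfig",
    "FactorData",
    "generate_factor_data",
    "generate_perfect_clusters",
    "generate_two_line_points",
    "generate_driver_metagene",
]


@dataclass
class GeneratorConfig:
    """Configuration of the factor-data generator.

    Defaults describe a mid-sized transcriptomic study: 2000 genes,
    200 samples, 10 strong expression programs each loading 5% of the
    genes with Laplace (super-gaussian) weights at unit scale over
    unit gaussian noise — an expected signal-variance fraction of 0.5,
    inside the 0.45–0.75 range observed for MSTD-dimension subspaces
    of real tumour transcriptomes.  Weak overlapping programs are off
    by default.
    """

    n_genes: int = 2000
    n_samples: int = 200
    k_sources: int = 10
    source_sparsity: float = 0.05
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    n_weak_programs: int = 0
    weak_support: int = 50
    weak_energy: float = 8.0
    n_small_geneset_components: int = 0
    small_geneset_sizes: tuple[int, ...] = (1, 2, 3)
    small_geneset_weight: tuple[float, float] = (8.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.source_sparsity <= 1:
            raise ValueError("source_sparsity must be in (0, 1]")
        if self.k_sources >= min(self.n_genes, self.n_samples):
            raise ValueError("k_sources must be < min(n_genes, n_samples)")
        if self.support_size < 1:
            raise ValueError("sparsity too low: sources would load no genes")
        if self.noise_sd < 0 or self.loading_scale <= 0:
            raise ValueError("scales must be positive")

    @property
    def support_size(self) -> int:
        return int(round(self.source_sparsity * self.n_genes))

    @property
    def source_energy(self) -> float:
        """Per-source sum of squared gene weights (fixed by construction)."""
        return self.support_size * 2.0 * self.loading_scale**2

    @property
    def expected_snr(self) -> float:
        """Strong-module signal variance over noise variance, per sample."""
        if self.noise_sd == 0:
            return math.inf
        signal = self.k_sources * self.source_energy
        return signal / (self.n_genes * self.noise_sd**2)


@dataclass
class FactorData:
    """Generator output: data plus ground truth for recovery tests."""

    X: ExpressionMatrix
    metagenes_true: pd.DataFrame
    mixing_true: pd.DataFrame
    small_geneset_drivers: dict[str, list[str]] = field(default_factory=dict)
    config: GeneratorConfig | None = None
    realized_snr: float | None = None


def _sparse_source(
    rng: np.random.Generator, n_genes: int, support: int, energy: float
) -> np.ndarray:
    idx = rng.choice(n_genes, size=support, replace=False)
    w = rng.laplace(scale=1.0, size=support)
    w *= math.sqrt(energy) / np.linalg.norm(w)
    out = np.zeros(n_genes)
    out[idx] = w
    return out


def generate_factor_data(cfg: GeneratorConfig) -> FactorData:
    """Draw X = S_true^T A_true^T + sparse part + noise, with ground truth.

    Strong sources load ``support_size`` genes each with Laplace weights
    rescaled to a fixed per-source energy (so the signal-to-noise ratio
    is set by the configuration, not the draw); loadings are unit
    gaussian.  Weak programs and planted small-gene-set components are
    appended the same way; only the k strong sources and the small-set
    components are reported as ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_sources
    S = np.vstack(
        [
            _sparse_source(rng, cfg.n_genes, cfg.support_size, cfg.source_energy)
            for _ in range(k)
        ]
    )
    A = rng.normal(size=(cfg.n_samples, k))
    X = S.T @ A.T
    noise = rng.normal(scale=cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    signal_var = float(np.sum(S**2))  # per-sample signal energy, E||a||^2 = 1
    X = X + noise

    if cfg.n_weak_programs:
        Sw = np.vstack(
            [
                _sparse_source(rng, cfg.n_genes, cfg.weak_support, cfg.weak_energy)
                for _ in range(cfg.n_weak_programs)
            ]
        )
        Aw = rng.normal(size=(cfg.n_samples, cfg.n_weak_programs))
        X = X + Sw.T @ Aw.T

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(cfg.n_samples)]
    drivers: dict[str, list[str]] = {}
    small_rows = []
    for c in range(cfg.n_small_geneset_components):
        size = int(rng.choice(cfg.small_geneset_sizes))
        idx = rng.choice(cfg.n_genes, size=size, replace=False)
        weights = rng.uniform(*cfg.small_geneset_weight, size=size)
        weights = np.sort(weights)[::-1] * rng.choice([-1.0, 1.0])
        row = np.zeros(cfg.n_genes)
        row[idx] = weights
        a = rng.normal(size=cfg.n_samples)
        X = X + np.outer(row, a)
        name = f"small{c + 1}"
        order = np.argsort(-np.abs(row[idx]))
        drivers[name] = [gene_ids[i] for i in idx[order]]
        small_rows.append((name, row, a))

    noise_var = float(np.sum(noise**2)) / cfg.n_samples
    realized_snr = math.inf if noise_var == 0 else signal_var / noise_var

    names = [f"source{i + 1}" for i in range(k)] + [n for n, _, _ in small_rows]
    S_all = np.vstack([S] + [r for _, r, _ in small_rows]) if small_rows else S
    A_all = (
        np.column_stack([A] + [a for _, _, a in small_rows]) if small_rows else A
    )
    return FactorData(
        X=ExpressionMatrix(X, gene_ids, sample_ids),
        metagenes_true=pd.DataFrame(S_all, index=names, columns=gene_ids),
        mixing_true=pd.DataFrame(A_all, index=sample_ids, columns=names),
        small_geneset_drivers=drivers,
        config=cfg,
        realized_snr=realized_snr,
    )


def generate_perfect_clusters(
    M: int, K: int, n_genes: int, seed: int | None = 0
) -> tuple[RawComponentSet, np.ndarray]:
    """K sign-flipped copies of M orthonormal metagenes, with labels.

    Realizes the analytic perfect-clustering case: |r| = 1 within each
    planted cluster and 0 across clusters (the basis vectors are
    zero-mean, so orthogonality is exactly zero correlation).  Returns
    the pooled component set (runs ordered, M components per run) and
    the planted cluster label of every row.
    """
    if M > n_genes - 1:
        raise ValueError("need n_genes > M for zero-mean orthonormal vectors")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_genes, M))
    raw -= raw.mean(axis=0)  # span orthogonal to the ones vector
    Q, _ = np.linalg.qr(raw)
    signs = rng.choice([-1.0, 1.0], size=(K, M))
    gene_rows = np.vstack([Q.T * signs[r][:, None] for r in range(K)])
    whitened_rows = np.vstack([np.eye(M) * signs[r][:, None] for r in range(K)])
    labels = np.tile(np.arange(M), K)
    comp_set = RawComponentSet(
        components=whitened_rows,
        gene_projections=gene_rows,
        run_index=np.repeat(np.arange(K), M),
        order=M,
        runs=K,
        seed=seed,
        converged=np.ones(K, dtype=bool),
        n_iterations=np.zeros(K, dtype=int),
        retries_used=np.zeros(K, dtype=int),
    )
    return comp_set, labels


#: Fixed moderate-tail magnitudes mirrored on both sides of a driver
#: metagene; they guarantee a non-empty 3-SD background tail with
#: internal gaps well under the driver gap.
MODERATE_TAIL = (4.2, 3.9, 3.6, 3.4)


def generate_driver_metagene(
    n_drivers: int,
    n_genes: int = 2000,
    seed: int | None = 0,
    driver_weight: tuple[float, float] = (8.0, 12.0),
) -> tuple[pd.Series, list[str]]:
    """Weight vector of a component driven by a small gene set.

    The planted drivers get weights drawn from ``driver_weight``
    (uniform on [8, 12) keeps the within-driver gap ratio below 1.5);
    the background is a symmetric pair of moderate tail genes
    (magnitudes 3.4–4.2 on both signs) plus gaussian bulk clipped to
    ±3, so the heaviest-tail side is decided by the drivers and the
    detector's gap sequence is deterministic: one large gap between
    the weakest driver and the strongest background tail gene.

    Returns the raw weight Series (gene-indexed) and the driver ids,
    ordered by descending weight.
    """
    if n_drivers < 1:
        raise ValueError("need at least one driver gene")
    rng = np.random.default_rng(seed)
    n_fixed = n_drivers + 2 * len(MODERATE_TAIL)
    if n_genes <= n_fixed:
        raise ValueError("n_genes too small for the fixture structure")
    bulk = np.clip(rng.normal(size=n_genes - n_fixed), -3.0, 3.0)
    drivers = np.sort(rng.uniform(*driver_weight, size=n_drivers))[::-1]
    tail = np.asarray(MODERATE_TAIL)
    w = np.concatenate([drivers, tail, -tail, bulk])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    series = pd.Series(w[np.argsort(perm)], index=genes)
    driver_ids = [genes[int(perm[i])] for i in range(n_drivers)]
    return series, driver_ids


def generate_two_line_points(
    line1: tuple[float, float],
    line2: tuple[float, float],
    n_per_line: int = 50,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    x_range1: tuple[float, float] = (0.0, 10.0),
    x_range2: tuple[float, float] = (0.0, 10.0),
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Labeled points along two (slope, intercept) lines plus the intersection.

    Gaussian noise of scale ``noise_sd`` is added along each line's
    normal, so at ``noise_sd=0`` every point lies exactly on its line.
    Returns (points, labels, analytic intersection).
    """
    (m1, b1), (m2, b2) = line1, line2
    if m1 == m2:
        raise ValueError("lines must have distinct slopes")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for lab, (m, b), (x0, x1) in ((0, line1, x_range1), (1, line2, x_range2)):
        x = rng.uniform(x0, x1, size=n_per_line)
        y = m * x + b
        normal = np.array([-m, 1.0]) / math.hypot(m, 1.0)
        offsets = rng.normal(scale=noise_sd, size=n_per_line) if noise_sd else 0.0
        p = np.column_stack([x, y]) + np.outer(
            offsets if np.ndim(offsets) else np.zeros(n_per_line), normal
        )
        pts.append(p)
        labels.append(np.full(n_per_line, lab))
    xi = (b2 - b1) / (m1 - m2)
    return np.vstack(pts), np.concatenate(labels), (xi, m1 * xi + b1)
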