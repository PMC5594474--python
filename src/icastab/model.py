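"""Stabilized ICA as a model/results pair.

:class:`StabilizedICA` holds the data and fit configuration;
:meth:`StabilizedICA.fit` runs the whole per-order protocol —
PCA-whitening, K fastICA restarts, 1-|r| clustering, stability indices,
centrotype extraction and orientation — and returns a
:class:`StabilizedICAResults` carrying the stability-ranked metagene
matrix S (components × genes), the mixing matrix A (samples ×
components), per-component stabilities and the explained-variance
fraction of the reduced subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_decomposition
from .ica import (
    DEFAULT_MAX_ITER,
    DEFAULT_RETRY_BUDGET,
    DEFAULT_TOL,
    cap_order,
    cluster_components,
    correlation_matrix,
    extract_centrotypes,
    run_multi_ica,
    stability_index,
    whiten_reduce,
)

__all__ = ["StabilizedICA", "StabilizedICAResults", "decompose_stabilized"]


class StabilizedICA:
    """Multi-run ICA model for a genes × samples expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame (genes × samples) or ndarray.
    gene_ids, sample_ids : identifiers, required for a bare ndarray.

    Examples
    --------
    >>> model = StabilizedICA.from_dataframe(frame)      # doctest: +SKIP
    >>> res = model.fit(n_components=20, n_runs=100, seed=0)  # doctest: +SKIP
    >>> res.metagenes.shape                               # doctest: +SKIP
    (20, n_genes)
    """

    def __init__(self, data, gene_ids=None, sample_ids=None):
        if isinstance(data, ExpressionMatrix):
            self.endog = data
        elif isinstance(data, pd.DataFrame):
            self.endog = ExpressionMatrix.from_frame(data)
        else:
            values = np.asarray(data, dtype=float)
            if gene_ids is None:
                gene_ids = [f"g{i}" for i in range(values.shape[0])]
            if sample_ids is None:
                sample_ids = [f"s{j}" for j in range(values.shape[1])]
            self.endog = ExpressionMatrix(values, list(gene_ids), list(sample_ids))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "StabilizedICA":
        return cls(frame)

    def fit(
        self,
        n_components: int,
        n_runs: int = 100,
        seed: int | None = None,
        *,
        linkage: str = "average",
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        retry_budget: int = DEFAULT_RETRY_BUDGET,
        strict: bool = False,
        tail_sd: float = 3.0,
        representative: str = "centrotype",
        apply_cap: bool = False,
    ) -> "StabilizedICAResults":
        """Fit the stabilized decomposition at one order.

        ``apply_cap`` silently lowers ``n_components`` to the
        0.9 × n_samples cap; when False an over-cap order raises.
        """
        X = self.endog
        M = int(n_components)
        cap = cap_order(M, X.n_samples)
        if M > cap:
            if apply_cap:
                M = cap
            else:
                raise ValueError(
                    f"M={M} exceeds the 0.9*n_samples cap ({cap}); "
                    "pass apply_cap=True to lower it automatically"
                )
        whitening = whiten_reduce(X, M)
        raw = run_multi_ica(
            X,
            M,
            n_runs,
            seed,
            whitening=whitening,
            tol=tol,
            max_iter=max_iter,
            retry_budget=retry_budget,
            strict=strict,
        )
        corr = correlation_matrix(raw)
        clusters = cluster_components(raw, corr=corr, linkage=linkage)
        stability_index(clusters, corr)
        centred = X.values - whitening.sample_means
        metagenes, mixing = extract_centrotypes(
            clusters,
            raw,
            corr=corr,
            data=centred,
            tail_sd=tail_sd,
            representative=representative,
        )
        stabilities = np.sort([c.stability for c in clusters])[::-1]
        names = [f"IC{i + 1}" for i in range(M)]
        params = {
            "linkage": linkage,
            "tol": tol,
            "max_iter": max_iter,
            "retry_budget": retry_budget,
            "tail_sd": tail_sd,
            "representative": representative,
        }
        return StabilizedICAResults(
            metagenes=pd.DataFrame(metagenes, index=names, columns=X.gene_ids),
            mixing=pd.DataFrame(mixing, index=X.sample_ids, columns=names),
            stabilities=stabilities,
            order=M,
            n_runs=n_runs,
            seed=seed,
            explained_variance_fraction=whitening.explained_variance_fraction,
            params=params,
            model=self,
            sample_means=whitening.sample_means,
            converged_runs=int(raw.converged.sum()),
            run_iterations=raw.n_iterations.copy(),
        )


@dataclass
class StabilizedICAResults:
    """Stabilized decomposition at one order M, stability-ranked.

    ``metagenes`` is the S matrix (components × genes; rows standardized
    to zero mean/unit variance over genes and oriented with the heaviest
    tail positive), ``mixing`` the A matrix (samples × components) such
    that the centred data ≈ ``metagenes.T @ mixing.T``.
    """

    metagenes: pd.DataFrame
    mixing: pd.DataFrame
    stabilities: np.ndarray
    order: int
    n_runs: int
    seed: int | None
    explained_variance_fraction: float
    params: dict[str, Any] = field(default_factory=dict)
    model: StabilizedICA | None = None
    sample_means: np.ndarray | None = None
    converged_runs: int | None = None
    run_iterations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stabilities = np.asarray(self.stabilities, dtype=float)
        if np.any(np.diff(self.stabilities) > 1e-12):
            raise ValueError("stabilities must be sorted non-increasing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.metagenes.columns)

    def average_stability(self, k="all") -> float:
        from .ica import average_stability

        return average_stability(self.stabilities, k)

    def metagene(self, component: int | str):
        """Return one component as a :class:`~icastab.compare.Metagene`."""
        from scipy.stats import kurtosis

        from .compare import Metagene

        if isinstance(component, str):
            rank = int(self.metagenes.index.get_loc(component)) + 1
        else:
            rank = int(component) + 1
        name = self.metagenes.index[rank - 1]
        weights = self.metagenes.loc[name]
        a_col = self.mixing[name].to_numpy()
        total = float(np.sum(self.mixing.to_numpy() ** 2))
        return Metagene(
            weights=weights,
            dataset=None,
            order=self.order,
            rank=rank,
            stability=float(self.stabilities[rank - 1]),
            kurtosis=float(kurtosis(weights.to_numpy())),
            explained_variance=float(np.sum(a_col**2) / total) if total else None,
        )

    def metagene_list(self, dataset: str | None = None):
        out = []
        for i in range(self.order):
            m = self.metagene(i)
            m.dataset = dataset
            out.append(m)
        return out

    def reconstruction(self) -> pd.DataFrame:
        """A·S mapped back to genes × samples (plus per-sample means)."""
        approx = self.metagenes.T.to_numpy() @ self.mixing.T.to_numpy()
        if self.sample_means is not None:
            approx = approx + self.sample_means
        return pd.DataFrame(
            approx, index=self.metagenes.columns, columns=self.mixing.index
        )

    def save(self, prefix) -> dict:
        return write_decomposition(self, prefix)

    def summary(self) -> str:
        lines = [
            "Stabilized ICA decomposition",
            f"  order M:              {self.order}",
            f"  runs K:               {self.n_runs}"
            + (
                f"  (converged: {self.converged_runs})"
                if self.converged_runs is not None
                else ""
            ),
            f"  seed:                 {self.seed}",
            f"  explained variance:   {self.explained_variance_fraction:.4f}",
            f"  avg stability S(M):   {self.average_stability():.4f}",
            "",
            "  component  stability",
        ]
        for name, iq in zip(self.metagenes.index, self.stabilities):
            lines.append(f"  {name:<9}  {iq:8.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<StabilizedICAResults M={self.order} K={self.n_runs} "
            f"S(M)={self.average_stability():.3f}>"
        )


def decompose_stabilized(
    X, M: int, K: int = 100, seed: int | None = None, **fit_kwargs
) -> StabilizedICAResults:
    """Functional form of :meth:`StabilizedICA.fit`."""
    return StabilizedICA(X).fit(n_components=M, n_runs=K, seed=seed, **fit_kwargs)
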