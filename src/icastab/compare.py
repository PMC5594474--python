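"""Metagene matching across decompositions and datasets.

Metagenes (gene-indexed component weight vectors) from different
decompositions are compared by the Pearson correlation of their weights
over common genes.  A component of set B is *best matched* to a query
from set A if it maximizes |r| over B; the pair is *reciprocal* when the
argmax holds in both directions.  Reciprocal pairs above a correlation
threshold form an undirected graph between datasets; the sum of a
node's incident edge correlations is its reproducibility score, bounded
by the number of other datasets.

The module also classifies the conservation of MSTD-level components in
higher-order decompositions (conserved / split / not conserved),
detects components driven by a small gene set via the multiplicative
gap in their heaviest weight tail, and annotates top-contributing genes
against reference gene sets (Jaccard index, hypergeometric tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .expression import GeneSetCollection
from .ica import orient_component

__all__ = [
    "Metagene",
    "MatchTable",
    "SmallGeneSetCall",
    "ConservationReport",
    "correlate_metagenes",
    "match_sets",
    "build_match_graph",
    "reproducibility_score",
    "rank_score_curve",
    "classify_conservation",
    "detect_small_geneset",
    "jaccard_top_genes",
    "hypergeom_enrich",
]

#: Default reciprocal-edge threshold on |r|.
EDGE_THRESHOLD = 0.3
#: Default floor on standardized weights defining top-contributing genes.
TOP_GENE_FLOOR = 5.0
#: Minimum common genes for a defined correlation.
MIN_COMMON_GENES = 10


@dataclass
class Metagene:
    """One component's gene weight vector, standardized and oriented.

    ``weights`` is a gene-indexed Series; on construction it is
    standardized to zero mean and unit variance over its gene universe
    and oriented so the heaviest |weight| > 3 tail is positive (both
    operations are idempotent).  ``source`` metadata identifies where
    the component came from.
    """

    weights: pd.Series
    dataset: str | None = None
    order: int | None = None
    rank: int | None = None
    stability: float | None = None
    kurtosis: float | None = None
    explained_variance: float | None = None

    def __post_init__(self) -> None:
        w = pd.Series(self.weights, dtype=float)
        if w.index.has_duplicates:
            raise ValueError("duplicate gene ids in metagene")
        self.weights = pd.Series(orient_component(w.to_numpy()), index=w.index)

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    def top_genes(self, floor: float = TOP_GENE_FLOOR) -> list[str]:
        """Genes with positive standardized weight above ``floor``."""
        sel = self.weights[self.weights > floor]
        return list(sel.sort_values(ascending=False).index)

    def label(self) -> str:
        ds = self.dataset if self.dataset is not None else "?"
        rk = self.rank if self.rank is not None else "?"
        return f"{ds}:IC{rk}"


def correlate_metagenes(
    a: Metagene,
    b: Metagene,
    restrict_3sd: bool = False,
    min_genes: int = MIN_COMMON_GENES,
) -> float:
    """Pearson correlation of two metagenes over their common genes.

    With ``restrict_3sd`` only genes whose standardized weight exceeds
    3 in absolute value *in the query metagene a* enter the correlation.
    Returns the signed r; ``nan`` (the undefined-match sentinel) when
    fewer than ``min_genes`` genes remain.
    """
    common = a.genes.intersection(b.genes)
    if restrict_3sd:
        heavy = a.weights.loc[common].abs() > 3.0
        common = common[heavy.to_numpy()]
    if len(common) < min_genes:
        return float("nan")
    x = a.weights.loc[common].to_numpy()
    y = b.weights.loc[common].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MatchTable:
    """Best matches of every query metagene into a target set.

    ``table`` has one row per query: target index, signed r, |r|, gap
    (best |r| / second-best |r|, inf when only one defined candidate)
    and the reciprocal flag (symmetric by construction).
    """

    table: pd.DataFrame
    queries: Sequence[Metagene] = field(repr=False, default=())
    targets: Sequence[Metagene] = field(repr=False, default=())

    def best(self, i: int) -> tuple[int, float]:
        row = self.table.iloc[i]
        return int(row["target"]), float(row["r"])

    def reciprocal_pairs(self) -> list[tuple[int, int, float]]:
        out = []
        for i, row in self.table.iterrows():
            if row["reciprocal"] and not np.isnan(row["r"]):
                out.append((int(i), int(row["target"]), float(row["r"])))
        return out


def _correlation_table(
    A: Sequence[Metagene], B: Sequence[Metagene], restrict_3sd: bool, min_genes: int
) -> np.ndarray:
    R = np.full((len(A), len(B)), np.nan)
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            R[i, j] = correlate_metagenes(
                a, b, restrict_3sd=restrict_3sd, min_genes=min_genes
            )
    return R


def _best_rows(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per row: argmax of |R| ignoring nan, and the best index (-1 if none)."""
    absR = np.abs(R)
    best = np.full(R.shape[0], -1)
    for i in range(R.shape[0]):
        row = absR[i]
        if np.all(np.isnan(row)):
            continue
        best[i] = int(np.nanargmax(row))
    return best, absR


def match_sets(
    A: Sequence[Metagene],
    B: Sequence[Metagene],
    restrict_3sd: bool = False,
    min_genes: int = MIN_COMMON_GENES,
) -> MatchTable:
    """Best-match every metagene of A into B and flag reciprocal pairs."""
    if not len(A) or not len(B):
        raise ValueError("both metagene sets must be non-empty")
    R_ab = _correlation_table(A, B, restrict_3sd, min_genes)
    R_ba = _correlation_table(B, A, restrict_3sd, min_genes)
    best_ab, abs_ab = _best_rows(R_ab)
    best_ba, _ = _best_rows(R_ba)
    rows = []
    for i in range(len(A)):
        j = best_ab[i]
        if j < 0:
            rows.append((i, -1, np.nan, np.nan, np.nan, False))
            continue
        r = R_ab[i, j]
        defined = abs_ab[i][~np.isnan(abs_ab[i])]
        if len(defined) > 1:
            second = float(np.sort(defined)[-2])
            gap = np.inf if second == 0 else float(abs(r)) / second
        else:
            gap = np.inf
        reciprocal = best_ba[j] == i
        rows.append((i, int(j), float(r), float(abs(r)), gap, bool(reciprocal)))
    table = pd.DataFrame(
        rows, columns=["query", "target", "r", "abs_r", "gap", "reciprocal"]
    ).set_index("query")
    return MatchTable(table=table, queries=tuple(A), targets=tuple(B))


def build_match_graph(
    decs: Iterable[tuple[str, Sequence[Metagene]]],
    threshold: float = EDGE_THRESHOLD,
    restrict_3sd: bool = False,
    min_genes: int = MIN_COMMON_GENES,
) -> nx.Graph:
    """Reciprocal-correlation graph across two or more datasets.

    Nodes are components keyed ``(dataset, index)`` with dataset, rank,
    stability and auxiliary-ranking attributes; edges are reciprocal
    best matches between *different* datasets with |r| above
    ``threshold`` (edge weight = |r|; the signed r is kept as an
    attribute).  Each node's reproducibility score (sum of incident
    edge weights) is stored as the ``reproducibility`` attribute.
    """
    decs = list(decs)
    if len(decs) < 2:
        raise ValueError("need at least 2 datasets")
    graph = nx.Graph()
    for ds, metas in decs:
        for idx, m in enumerate(metas):
            graph.add_node(
                (ds, idx),
                dataset=ds,
                rank=m.rank if m.rank is not None else idx + 1,
                stability=m.stability,
                order=m.order,
                kurtosis=m.kurtosis,
                explained_variance=m.explained_variance,
            )
    for p in range(len(decs)):
        for q in range(p + 1, len(decs)):
            ds_a, A = decs[p]
            ds_b, B = decs[q]
            mt = match_sets(A, B, restrict_3sd=restrict_3sd, min_genes=min_genes)
            for i, j, r in mt.reciprocal_pairs():
                if abs(r) > threshold:
                    graph.add_edge(
                        (ds_a, i), (ds_b, j), weight=float(abs(r)), r=float(r)
                    )
    # auxiliary rankings within each dataset (used by rank_score_curve)
    for ds, metas in decs:
        for attr, rank_attr in (
            ("kurtosis", "kurtosis_rank"),
            ("explained_variance", "variance_rank"),
        ):
            vals = [m.__getattribute__(attr) for m in metas]
            if any(v is None for v in vals):
                continue
            order = np.argsort(np.argsort(-np.asarray(vals))) + 1
            for idx, rk in enumerate(order):
                graph.nodes[(ds, idx)][rank_attr] = int(rk)
    for node in graph.nodes:
        graph.nodes[node]["reproducibility"] = reproducibility_score(graph, node)
    return graph


def reproducibility_score(graph: nx.Graph, node) -> float:
    """Sum of reciprocal-edge |r| incident to a node."""
    if node not in graph:
        raise KeyError(node)
    return float(sum(d["weight"] for _, _, d in graph.edges(node, data=True)))


def rank_score_curve(
    graph: nx.Graph,
    ranking: str = "stability",
    relative_to_mstd: bool = False,
    mstd: dict[str, int] | None = None,
) -> pd.Series:
    """Mean reproducibility score per component rank.

    ``ranking`` is one of ``stability`` (the node's native rank),
    ``kurtosis`` or ``variance`` (auxiliary ranks).  With
    ``relative_to_mstd`` the x-axis is rank − MSTD of the node's
    dataset (``mstd`` must then map dataset → MSTD).
    """
    attr = {
        "stability": "rank",
        "kurtosis": "kurtosis_rank",
        "variance": "variance_rank",
    }.get(ranking)
    if attr is None:
        raise ValueError(f"unknown ranking {ranking!r}")
    if relative_to_mstd and mstd is None:
        raise ValueError("relative_to_mstd requires per-dataset MSTD values")
    xs, scores = [], []
    for node, data in graph.nodes(data=True):
        if attr not in data:
            raise ValueError(f"node {node} lacks attribute {attr!r}")
        x = data[attr]
        if relative_to_mstd:
            x = x - mstd[data["dataset"]]
        xs.append(x)
        scores.append(data["reproducibility"])
    series = pd.Series(scores, index=pd.Index(xs, name="rank")).groupby(level=0).mean()
    series.name = f"mean_reproducibility_{ranking}"
    return series


@dataclass
class ConservationReport:
    """Conservation classes of MSTD-level components in a higher order.

    ``table``: per low-order component the class (conserved / split /
    not_conserved), the matched high-order component and its r.
    ``frequencies``: class → fraction over low components (sums to 1;
    split takes precedence over conserved).  ``high_corr_fraction``:
    fraction of low components reciprocally matched with |r| above the
    high tier (0.8 by default).
    """

    table: pd.DataFrame
    frequencies: dict[str, float]
    threshold: float
    high_tier: float
    high_corr_fraction: float


def _as_metagenes(obj, dataset=None) -> list[Metagene]:
    if hasattr(obj, "metagene_list"):
        return obj.metagene_list(dataset)
    return list(obj)


def classify_conservation(
    low,
    high,
    threshold: float = EDGE_THRESHOLD,
    high_tier: float = 0.8,
    min_genes: int = MIN_COMMON_GENES,
) -> ConservationReport:
    """Classify each low-order component against a higher-order decomposition.

    conserved — reciprocal best match in the high set with |r| >
    threshold; split — conserved and additionally at least one *other*
    high component non-reciprocally best-matches it with |r| >
    threshold (a component splitting into several); not_conserved —
    everything else.  Classes are exclusive with precedence
    split > conserved > not_conserved.
    """
    low_m = _as_metagenes(low)
    high_m = _as_metagenes(high)
    if hasattr(low, "order") and hasattr(high, "order") and high.order <= low.order:
        raise ValueError("high-order decomposition must have larger order")
    lo_hi = match_sets(low_m, high_m, min_genes=min_genes)
    hi_lo = match_sets(high_m, low_m, min_genes=min_genes)
    rows = []
    for i in range(len(low_m)):
        row = lo_hi.table.loc[i]
        reciprocal = bool(row["reciprocal"]) and row["abs_r"] > threshold
        extras = [
            j
            for j in range(len(high_m))
            if hi_lo.table.loc[j, "target"] == i
            and not hi_lo.table.loc[j, "reciprocal"]
            and hi_lo.table.loc[j, "abs_r"] > threshold
        ]
        if reciprocal and extras:
            cls = "split"
        elif reciprocal:
            cls = "conserved"
        else:
            cls = "not_conserved"
        rows.append(
            {
                "component": i,
                "class": cls,
                "matched": int(row["target"]),
                "r": float(row["r"]),
                "abs_r": float(row["abs_r"]),
                "n_extra_matches": len(extras),
            }
        )
    table = pd.DataFrame(rows).set_index("component")
    n = len(table)
    freqs = {
        cls: float((table["class"] == cls).sum()) / n
        for cls in ("conserved", "split", "not_conserved")
    }
    high_corr = float(
        ((table["class"] != "not_conserved") & (table["abs_r"] > high_tier)).sum() / n
    )
    return ConservationReport(
        table=table,
        frequencies=freqs,
        threshold=threshold,
        high_tier=high_tier,
        high_corr_fraction=high_corr,
    )


@dataclass
class SmallGeneSetCall:
    """Verdict on whether a few genes drive a component.

    ``driven`` with the ordered ``driver_genes`` when the heaviest
    weight tail contains genes separated from the rest by exactly one
    multiplicative gap above ``g_max``; a single gene beyond ``w_top``
    counts as a single-outlier driver.
    """

    driven: bool
    driver_genes: list[str]
    heaviest_tail: str
    tail_weights: tuple[float, float]
    gaps: list[float]
    w_top: float
    g_max: float


def detect_small_geneset(
    m: Metagene, w_top: float = 3.0, g_max: float = 1.5
) -> SmallGeneSetCall:
    """Detect a small-gene-set-driven component from its weight tails.

    The tail weight on each side is the total |weight| of genes beyond
    ``w_top`` standardized units; in the heavier tail the genes P beyond
    the threshold are sorted by descending |weight| and the gaps
    ``G_i = |W_i| / |W_{i+1}|`` examined.  The component is driven iff
    exactly one gap exceeds ``g_max`` (drivers = genes ranked at or
    above the gap), or iff P is a single gene.
    """
    w = m.weights
    pos = w[w > w_top]
    neg = w[w < -w_top]
    pos_weight = float(pos.abs().sum())
    neg_weight = float(neg.abs().sum())
    side = "positive" if pos_weight >= neg_weight else "negative"
    tail = pos if side == "positive" else neg
    tail = tail.abs().sort_values(ascending=False)
    gaps = (
        (tail.to_numpy()[:-1] / tail.to_numpy()[1:]).tolist() if len(tail) > 1 else []
    )
    if len(tail) == 0:
        driven, drivers = False, []
    elif len(tail) == 1:
        driven, drivers = True, list(tail.index)
    else:
        over = [i for i, g in enumerate(gaps) if g > g_max]
        if len(over) == 1:
            driven = True
            drivers = list(tail.index[: over[0] + 1])
        else:
            driven, drivers = False, []
    return SmallGeneSetCall(
        driven=driven,
        driver_genes=drivers,
        heaviest_tail=side,
        tail_weights=(pos_weight, neg_weight),
        gaps=gaps,
        w_top=w_top,
        g_max=g_max,
    )


def jaccard_top_genes(
    m: Metagene, ref: Iterable[str], weight_floor: float = TOP_GENE_FLOOR
) -> float:
    """Jaccard index between a reference set and the top-contributing genes.

    Top-contributing genes have positive standardized weight above
    ``weight_floor``.  Returns ``nan`` when both sets are empty.
    """
    top = set(m.top_genes(weight_floor))
    ref = set(ref)
    union = top | ref
    if not union:
        return float("nan")
    return len(top & ref) / len(union)


def hypergeom_enrich(
    m: Metagene,
    sets: GeneSetCollection,
    weight_floor: float = TOP_GENE_FLOOR,
    correction: str | None = "bh",
) -> pd.DataFrame:
    """Hypergeometric enrichment of top-contributing genes in reference sets.

    The universe is the metagene's gene list; the drawn sample is the
    top-contributing genes (weight > ``weight_floor``).  For each
    reference set the upper-tail hypergeometric p-value of the overlap
    is computed; Benjamini–Hochberg adjusted p-values are added unless
    ``correction`` is None.  A reference set disjoint from the universe
    gets p = 1 with a warning.
    """
    universe = m.genes
    N = len(universe)
    top = set(m.top_genes(weight_floor))
    n_draw = len(top)
    rows = []
    for name in sets:
        members = set(sets.members(name)) & set(universe)
        K = len(members)
        k = len(members & top)
        if K == 0:
            warnings.warn(
                f"gene set {name!r} shares no genes with the universe", UserWarning
            )
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, N, K, n_draw))
        rows.append({"set": name, "overlap": k, "set_size": K, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    if correction is not None:
        if correction != "bh":
            raise ValueError("only Benjamini-Hochberg ('bh') correction is supported")
        out["p_adj"] = (
            false_discovery_control(out["p"].to_numpy(), method="bh")
            if len(out)
            else []
        )
    return out.sort_values("p")
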