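"""Order scanning and the Maximally Stable Transcriptome Dimension.

A stabilized decomposition is computed at every order M on a grid (by
default 2–50 step 1 then 55–100 step 5, capped at 0.9 × n_samples) and
only the stability profiles are retained.  Overlaying all profiles as
(rank, stability) points yields a cloud with two regimes: approximately
uniformly distributed stabilities up to the effective dimension, and a
mode of low-stability components beyond it.  Two-line clustering of the
cloud separates the regimes; the x-coordinate of the line intersection,
rounded and clamped to the grid, is the MSTD — the largest order at
which the decomposition does not yet produce a large proportion of
highly unstable components.

Classical PCA-based dimension estimates (Kaiser rule, broken-stick) are
provided as baselines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .expression import ExpressionMatrix
from .ica import average_stability, cap_order
from .klines import KLinesFit, Line, kline_cluster, line_intersection
from .model import StabilizedICA

__all__ = [
    "DEFAULT_GRID",
    "StabilityProfile",
    "StabilityScan",
    "MSTDResult",
    "scan_orders",
    "profile_points",
    "estimate_mstd",
    "kaiser_rule",
    "broken_stick",
    "baseline_dimensions",
    "DimensionScan",
    "DimensionScanResults",
    "plot_stability_profiles",
]

#: Default order grid: every order from 2 to 50, then steps of 5 to 100.
DEFAULT_GRID: tuple[int, ...] = tuple(range(2, 51)) + tuple(range(55, 101, 5))

#: Stability below which a component counts as "low-stability" for the
#: parallel-line fallback (the observed low-stability band is 0.2–0.4).
LOW_STABILITY = 0.4


@dataclass
class StabilityProfile:
    """Stability indices of one decomposition, sorted non-increasing."""

    order: int
    stabilities: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.stabilities, dtype=float)
        self.stabilities = np.sort(vals)[::-1]
        if len(self.stabilities) != self.order:
            raise ValueError("profile length must equal the order")

    @property
    def s_total(self) -> float:
        """Average stability S(M) over all M components."""
        return float(self.stabilities.mean())

    def average(self, k="all") -> float:
        """Average stability of the top-k components, S_M(k)."""
        return average_stability(self.stabilities, k)


@dataclass
class StabilityScan:
    """Stability profiles over a grid of decomposition orders."""

    profiles: list[StabilityProfile]
    grid: tuple[int, ...]
    cap_applied: bool = False
    failed_orders: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = tuple(int(m) for m in self.grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        self.grid = grid
        by_order = {p.order for p in self.profiles}
        expected = set(grid) - set(self.failed_orders)
        if by_order != expected:
            raise ValueError("one profile required per successful grid order")
        self.profiles = sorted(self.profiles, key=lambda p: p.order)

    @property
    def orders(self) -> list[int]:
        return [p.order for p in self.profiles]

    def profile(self, order: int) -> StabilityProfile:
        for p in self.profiles:
            if p.order == order:
                return p
        raise KeyError(order)

    def s_total_curve(self) -> dict[int, float]:
        return {p.order: p.s_total for p in self.profiles}


def _capped_grid(grid, n_samples) -> tuple[tuple[int, ...], bool]:
    grid = sorted(set(int(m) for m in grid))
    if not grid or grid[0] < 2:
        raise ValueError("grid orders must be >= 2")
    cap = cap_order(max(grid), n_samples)
    capped = sorted(set(min(m, cap) for m in grid))
    return tuple(capped), capped != tuple(grid)


def scan_orders(
    X,
    grid=DEFAULT_GRID,
    K: int = 100,
    seed: int | None = None,
    *,
    cache_dir=None,
    **fit_kwargs,
) -> StabilityScan:
    """One stabilized decomposition per grid order, keeping the profiles.

    Orders above the 0.9 × n_samples cap are lowered to the cap (and
    deduplicated).  A failing order is recorded in ``failed_orders`` and
    skipped rather than aborting the scan.  With ``cache_dir`` set, the
    full decomposition of every order is also written to disk.
    """
    model = StabilizedICA(X)
    grid, cap_applied = _capped_grid(grid, model.endog.n_samples)
    profiles: list[StabilityProfile] = []
    failed: dict[int, str] = {}
    for M in grid:
        try:
            res = model.fit(n_components=M, n_runs=K, seed=seed, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - per-order isolation
            warnings.warn(f"order M={M} failed and is excluded: {exc}", UserWarning)
            failed[M] = str(exc)
            continue
        profiles.append(StabilityProfile(order=M, stabilities=res.stabilities))
        if cache_dir is not None:
            from pathlib import Path

            res.save(Path(cache_dir) / f"dec_M{M}_K{K}_seed{seed}")
    return StabilityScan(
        profiles=profiles, grid=grid, cap_applied=cap_applied, failed_orders=failed
    )


def profile_points(scan: StabilityScan) -> np.ndarray:
    """Overlay all profiles as (rank, stability) points, ranks 1-based."""
    if not scan.profiles:
        raise ValueError("empty scan")
    pts = [
        (rank, iq)
        for p in scan.profiles
        for rank, iq in enumerate(p.stabilities, start=1)
    ]
    return np.asarray(pts, dtype=float)


@dataclass
class MSTDResult:
    """MSTD estimate with the two-line fit behind it.

    ``mstd`` is the rounded line-intersection x clamped to the grid
    range; ``mstd_grid`` is the nearest order actually scanned.
    ``method`` is ``"two-line"`` normally and
    ``"low-stability-fraction"`` when the fitted lines were parallel and
    the fallback (first order whose low-stability fraction exceeds 50%)
    was used — a heuristic, flagged here.
    """

    mstd: int
    mstd_grid: int
    fit: KLinesFit | None
    scan: StabilityScan
    intersection: tuple[float, float] | None = None
    method: str = "two-line"

    def summary(self) -> str:
        lines = [
            "MSTD estimate",
            f"  mstd:              {self.mstd}",
            f"  nearest grid order: {self.mstd_grid}",
            f"  method:            {self.method}",
        ]
        if self.intersection is not None:
            lines.append(
                f"  line intersection: x={self.intersection[0]:.3f}, "
                f"y={self.intersection[1]:.3f}"
            )
        if self.fit is not None:
            s1, b1 = self.fit.line_steep
            s2, b2 = self.fit.line_flat
            lines.append(f"  steep line:        y = {s1:.5f} x + {b1:.4f}")
            lines.append(f"  flat line:         y = {s2:.5f} x + {b2:.4f}")
        return "\n".join(lines)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _split_inits(Pn: np.ndarray, grid_norm: np.ndarray):
    """Regime-split initializations: TLS lines left/right of each order."""
    from .klines import fit_line_tls

    for g in grid_norm:
        left = Pn[Pn[:, 0] <= g]
        right = Pn[Pn[:, 0] > g]
        if len(left) >= 2 and len(right) >= 2:
            try:
                yield (fit_line_tls(left), fit_line_tls(right))
            except ValueError:
                continue


def estimate_mstd(scan: StabilityScan) -> MSTDResult:
    """MSTD from the two-line clustering of the overlaid profiles.

    The point cloud is rescaled to its bounding box before clustering
    (ranks span up to ~100 while stabilities live in [0, 1]; raw
    orthogonal distances would be dominated by the rank axis); fitted
    lines are mapped back to data coordinates for the intersection.

    The alternating two-line fit is a local search, so it is run from
    several deterministic initializations — the axis-matching lines
    plus regime-split starts (total-least-squares lines fitted left and
    right of each scanned order) — and the lowest-objective solution
    whose intersection lies inside the scanned range is kept.  If every
    solution is parallel or intersects outside the grid, the estimate
    falls back to the first order whose fraction of low-stability
    components (I_q < 0.4) exceeds 50%.
    """
    if len(scan.profiles) < 3:
        raise ValueError("need at least 3 profiles to estimate MSTD")
    P = profile_points(scan)
    lo, hi = P.min(axis=0), P.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Pn = (P - lo) / span
    m_lo, m_hi = min(scan.orders), max(scan.orders)
    grid_norm = (np.asarray(scan.orders, dtype=float) - lo[0]) / span[0]

    candidates = []
    inits = [None, *_split_inits(Pn, grid_norm)]
    for init in inits:
        try:
            fit = kline_cluster(Pn, init_lines=init)
        except (ValueError, RuntimeError):
            continue
        steep, flat = (ln.transformed(span, lo) for ln in fit.lines)
        try:
            ix, iy = line_intersection(steep, flat)
            valid = m_lo <= float(ix) <= m_hi
        except ValueError:
            ix = iy = None
            valid = False
        candidates.append((fit, steep, flat, ix, iy, valid))
    if not candidates:
        return _fallback_mstd(scan, None)

    valid_candidates = [c for c in candidates if c[5]]
    if not valid_candidates:
        best = min(candidates, key=lambda c: c[0].objective)
        return _fallback_mstd(scan, _fit_in_data_coords(best))
    best = min(valid_candidates, key=lambda c: c[0].objective)
    fit, steep, flat, ix, iy, _ = best
    mstd = min(max(_round_half_up(float(ix)), m_lo), m_hi)
    nearest = min(scan.orders, key=lambda m: (abs(m - mstd), m))
    return MSTDResult(
        mstd=mstd,
        mstd_grid=nearest,
        fit=_fit_in_data_coords(best),
        scan=scan,
        intersection=(float(ix), float(iy)),
        method="two-line",
    )


def _fit_in_data_coords(candidate) -> KLinesFit:
    fit, steep, flat, *_ = candidate
    return KLinesFit(
        line_steep=(steep.slope, steep.intercept),
        line_flat=(flat.slope, flat.intercept),
        assignments=fit.assignments,
        iterations=fit.iterations,
        converged=fit.converged,
        objective=fit.objective,
        lines=(steep, flat),
        degenerate=fit.degenerate,
    )


def _fallback_mstd(scan: StabilityScan, fit: KLinesFit | None) -> MSTDResult:
    chosen = max(scan.orders)
    for p in scan.profiles:
        if np.mean(p.stabilities < LOW_STABILITY) > 0.5:
            chosen = p.order
            break
    warnings.warn(
        "two-line fit degenerate (parallel lines); falling back to the first "
        f"order with >50% components below I_q={LOW_STABILITY}",
        UserWarning,
    )
    return MSTDResult(
        mstd=chosen,
        mstd_grid=chosen,
        fit=fit,
        scan=scan,
        intersection=None,
        method="low-stability-fraction",
    )


def kaiser_rule(eigenvalues) -> int:
    """Number of covariance eigenvalues above the mean eigenvalue."""
    vals = np.asarray(eigenvalues, dtype=float)
    if vals.size == 0:
        return 0
    return int(np.sum(vals > vals.mean()))


def broken_stick(eigenvalues) -> int:
    """Largest k with all top-k variance proportions above broken-stick expectations.

    The broken-stick expectation for rank j among p pieces is
    ``b_j = (1/p) * sum_{i=j}^{p} 1/i``.
    """
    vals = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    p = len(vals)
    if p == 0 or vals.sum() <= 0:
        return 0
    props = vals / vals.sum()
    inv = 1.0 / np.arange(1, p + 1)
    b = np.cumsum(inv[::-1])[::-1] / p
    above = props > b
    k = 0
    while k < p and above[k]:
        k += 1
    return k


def _covariance_spectrum(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    centred = values - values.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s**2 / (values.shape[0] - 1)


def baseline_dimensions(X) -> dict[str, int]:
    """Kaiser-rule and broken-stick dimension estimates for an expression matrix."""
    spectrum = _covariance_spectrum(X)
    return {
        "kaiser": kaiser_rule(spectrum),
        "broken_stick": broken_stick(spectrum),
    }


class DimensionScan:
    """Model selecting the decomposition order of an expression matrix.

    ``fit`` scans the order grid with K fastICA restarts per order and
    returns a :class:`DimensionScanResults` with the MSTD estimate and
    the PCA baselines.
    """

    def __init__(self, data, grid=DEFAULT_GRID):
        self.model = StabilizedICA(data)
        self.grid = tuple(grid)

    @classmethod
    def from_dataframe(cls, frame, grid=DEFAULT_GRID) -> "DimensionScan":
        return cls(frame, grid=grid)

    def fit(
        self, n_runs: int = 100, seed: int | None = None, **fit_kwargs
    ) -> "DimensionScanResults":
        scan = scan_orders(
            self.model.endog, grid=self.grid, K=n_runs, seed=seed, **fit_kwargs
        )
        mstd = estimate_mstd(scan)
        baselines = baseline_dimensions(self.model.endog)
        return DimensionScanResults(
            scan=scan,
            mstd_result=mstd,
            baselines=baselines,
            n_runs=n_runs,
            seed=seed,
            model=self,
        )


@dataclass
class DimensionScanResults:
    """Stability scan plus the MSTD and baseline dimension estimates."""

    scan: StabilityScan
    mstd_result: MSTDResult
    baselines: dict[str, int]
    n_runs: int
    seed: int | None
    model: DimensionScan | None = None

    @property
    def mstd(self) -> int:
        return self.mstd_result.mstd

    def summary(self) -> str:
        curve = self.scan.s_total_curve()
        lines = [
            "Decomposition-order scan",
            f"  grid:            {self.scan.grid[0]}..{self.scan.grid[-1]}"
            f" ({len(self.scan.grid)} orders"
            + (", cap applied)" if self.scan.cap_applied else ")"),
            f"  runs per order:  {self.n_runs}",
            f"  seed:            {self.seed}",
            f"  Kaiser rule:     {self.baselines['kaiser']}",
            f"  broken stick:    {self.baselines['broken_stick']}",
            "",
            self.mstd_result.summary(),
            "",
            "  M    S(M)",
        ]
        for m, s in curve.items():
            lines.append(f"  {m:<4} {s:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        return plot_stability_profiles(self.scan, self.mstd_result, ax=ax)

    def to_dict(self) -> dict[str, Any]:
        fit = self.mstd_result.fit
        return {
            "mstd": self.mstd,
            "mstd_grid": self.mstd_result.mstd_grid,
            "method": self.mstd_result.method,
            "intersection": self.mstd_result.intersection,
            "lines": None
            if fit is None
            else {"steep": list(fit.line_steep), "flat": list(fit.line_flat)},
            "grid": list(self.scan.grid),
            "cap_applied": self.scan.cap_applied,
            "failed_orders": dict(self.scan.failed_orders),
            "baselines": dict(self.baselines),
            "profiles": {p.order: p.stabilities.tolist() for p in self.scan.profiles},
            "n_runs": self.n_runs,
            "seed": self.seed,
        }


def plot_stability_profiles(scan: StabilityScan, mstd: MSTDResult | None = None, ax=None):
    """Grey overlaid stability profiles, fitted lines and the MSTD marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for p in scan.profiles:
        ax.plot(
            np.arange(1, p.order + 1), p.stabilities, color="0.6", lw=0.7, alpha=0.6
        )
    if mstd is not None and mstd.fit is not None:
        xs = np.linspace(1, max(scan.orders), 200)
        for (slope, intercept), style, label in (
            (mstd.fit.line_steep, "b--", "steep line"),
            (mstd.fit.line_flat, "r--", "flat line"),
        ):
            if np.isfinite(slope):
                ax.plot(xs, slope * xs + intercept, style, lw=1.2, label=label)
        ax.axvline(mstd.mstd, color="k", ls=":", lw=1.2, label=f"MSTD = {mstd.mstd}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("component stability rank")
    ax.set_ylabel("stability index $I_q$")
    ax.set_ylim(-0.05, 1.05)
    return ax
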