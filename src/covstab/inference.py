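"""Permutation inference between group networks and the strength correction.

The group network is a statistic of the subject set, so exchangeability holds
at the subject level: a permutation re-splits the pooled subjects into two
groups of the original sizes, rebuilds both networks and recomputes the metric
difference.  Two-tailed p-values use the plus-one estimator
p = (1 + #{|perm| >= |observed|}) / (n_perm + 1), which is never zero.

The average-strength correction regresses each weighted metric on the average
strength across group compositions (pooled over groups) and re-assesses the
group difference on the residuals; if strength drives a metric's group
difference, the adjusted difference vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import (
    adjacency_from_order,
    edge_count_at_density,
    edge_order,
    pearson_connectivity,
)
from .exceptions import (
    DegeneratePermutationError,
    ParameterError,
    ZeroVarianceError,
)
from .metrics import (
    BINARY_METRICS,
    WEIGHTED_METRICS,
    average_strength_from_weights,
    binary_distances,
    clustering_from_nodal,
    efficiency_from_distances,
    path_length_from_distances,
    transitivity_from_nodal,
    triangles_and_degrees,
    weighted_distances,
)

__all__ = [
    "MetricSpec",
    "PermutationTestResult",
    "StrengthAdjustedResult",
    "evaluate_specs",
    "permutation_stats",
    "pvalue_plus_one",
    "permutation_test",
    "strength_adjust",
]


@dataclass(frozen=True)
class MetricSpec:
    """One metric to evaluate: name, graph mode, and density (binary only)."""

    metric: str
    mode: str  # "binary" | "weighted"
    density: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "binary":
            if self.metric not in BINARY_METRICS:
                raise ParameterError(
                    f"metric {self.metric!r} is not computed for binary graphs "
                    "(characteristic path length requires full connectedness)"
                )
            if self.density is None or not 0.0 < self.density < 1.0:
                raise ParameterError("binary metric requires density in (0, 1)")
        elif self.mode == "weighted":
            if self.metric not in WEIGHTED_METRICS:
                raise ParameterError(f"unknown weighted metric {self.metric!r}")
            if self.density is not None:
                raise ParameterError("weighted metrics take no density")
        else:
            raise ParameterError(f"mode must be 'binary' or 'weighted', got {self.mode!r}")


def evaluate_specs(X: np.ndarray, specs: list[MetricSpec]) -> np.ndarray:
    """Metric values for one subject subset, sharing the correlation matrix.

    Builds the Pearson connectivity once, derives the binary graphs per
    requested density from a single edge ranking, and computes distances only
    when a path-based metric asks for them.
    """
    r = pearson_connectivity(X)
    n = r.shape[0]
    out = np.empty(len(specs))

    bin_densities = sorted({s.density for s in specs if s.mode == "binary"})
    bin_cache: dict[float, dict] = {}
    if bin_densities:
        i_sorted, j_sorted, _ = edge_order(r)
        for d in bin_densities:
            A = adjacency_from_order(i_sorted, j_sorted, edge_count_at_density(d, n), n)
            bin_cache[d] = {"A": A}

    w_cache: dict = {}
    need_weighted = any(s.mode == "weighted" for s in specs)
    if need_weighted:
        w_cache["W"] = np.abs(r)

    def _bin_nodal(d):
        c = bin_cache[d]
        if "tk" not in c:
            c["tk"] = triangles_and_degrees(c["A"], weighted=False)
        return c["tk"]

    def _bin_dist(d):
        c = bin_cache[d]
        if "D" not in c:
            c["D"] = binary_distances(c["A"])
        return c["D"]

    def _w_nodal():
        if "tk" not in w_cache:
            w_cache["tk"] = triangles_and_degrees(w_cache["W"], weighted=True)
        return w_cache["tk"]

    def _w_dist():
        if "D" not in w_cache:
            w_cache["D"] = weighted_distances(w_cache["W"])
        return w_cache["D"]

    for idx, s in enumerate(specs):
        if s.mode == "binary":
            if s.metric == "global_efficiency":
                out[idx] = efficiency_from_distances(_bin_dist(s.density))
            elif s.metric == "clustering":
                out[idx] = clustering_from_nodal(*_bin_nodal(s.density))
            else:  # transitivity
                out[idx] = transitivity_from_nodal(*_bin_nodal(s.density))
        else:
            if s.metric == "average_strength":
                out[idx] = average_strength_from_weights(w_cache["W"])
            elif s.metric == "char_path_length":
                out[idx] = path_length_from_distances(_w_dist())
            elif s.metric == "global_efficiency":
                out[idx] = efficiency_from_distances(_w_dist())
            elif s.metric == "clustering":
                out[idx] = clustering_from_nodal(*_w_nodal())
            else:  # transitivity
                out[idx] = transitivity_from_nodal(*_w_nodal())
    return out


def pvalue_plus_one(observed: float, perm_stats: np.ndarray) -> float:
    """Two-tailed plus-one permutation p-value; always in (0, 1]."""
    perm_stats = np.asarray(perm_stats, dtype=float)
    return float(
        (1 + (np.abs(perm_stats) >= abs(observed)).sum()) / (perm_stats.size + 1)
    )


def permutation_stats(
    XA: np.ndarray,
    XB: np.ndarray,
    eval_fn,
    n_perm: int,
    rng: np.random.Generator,
    max_redraw: int = 100,
):
    """Observed difference and permutation differences for a vector statistic.

    ``eval_fn`` maps a subjects x regions array to a vector of metric values.
    Permutations re-split the pooled rows into groups of the original sizes;
    a split that leaves a region with zero variance is redrawn (up to
    ``max_redraw`` consecutive times).
    """
    XA = np.asarray(XA, dtype=float)
    XB = np.asarray(XB, dtype=float)
    observed = eval_fn(XA) - eval_fn(XB)
    pooled = np.vstack([XA, XB])
    n_a, total = XA.shape[0], pooled.shape[0]
    perm = np.empty((n_perm, observed.size))
    for p in range(n_perm):
        redraws = 0
        while True:
            idx = rng.permutation(total)
            try:
                perm[p] = eval_fn(pooled[idx[:n_a]]) - eval_fn(pooled[idx[n_a:]])
                break
            except ZeroVarianceError:
                redraws += 1
                if redraws > max_redraw:
                    raise DegeneratePermutationError(
                        f"{max_redraw} consecutive degenerate permutation splits"
                    )
    return observed, perm


@dataclass
class PermutationTestResult:
    """Observed group difference (A - B) and its two-tailed plus-one p-value."""

    metric_spec: MetricSpec
    observed: float
    pvalue: float
    n_perm: int
    seed: int


def _as_matrix(residuals) -> np.ndarray:
    if isinstance(residuals, np.ndarray):
        return np.asarray(residuals, dtype=float)
    if hasattr(residuals, "values") and callable(residuals.values):
        return residuals.values()
    return np.asarray(residuals, dtype=float)


def permutation_test(
    residuals_A,
    residuals_B,
    metric_spec: MetricSpec | list[MetricSpec],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult | list[PermutationTestResult]:
    """Subject-level permutation test of a group difference in graph metrics.

    ``residuals_A`` and ``residuals_B`` are equally sized subjects x regions
    residual arrays (or ResidualTable objects).  Multiple metric specs share
    one set of permutations.
    """
    XA, XB = _as_matrix(residuals_A), _as_matrix(residuals_B)
    if XA.shape[0] != XB.shape[0]:
        raise ParameterError("groups must be equally sized for the permutation test")
    if XA.shape[0] < 3:
        raise ParameterError("permutation test requires >= 3 subjects per group")
    single = isinstance(metric_spec, MetricSpec)
    specs = [metric_spec] if single else list(metric_spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    observed, perm = permutation_stats(
        XA, XB, lambda X: evaluate_specs(X, specs), n_perm, rng
    )
    results = [
        PermutationTestResult(
            metric_spec=s,
            observed=float(observed[i]),
            pvalue=pvalue_plus_one(observed[i], perm[:, i]),
            n_perm=n_perm,
            seed=seed,
        )
        for i, s in enumerate(specs)
    ]
    return results[0] if single else results


# -------------------------------------------------- average-strength correction


@dataclass
class StrengthAdjustedResult:
    """Weighted metrics residualized on average strength, with adjusted tests.

    ``adjusted`` holds per (composition, size, metric, group) residual values;
    ``pvalues`` one label-permutation p-value per (size, metric) for the
    difference of group means of the residuals.
    """

    adjusted: pd.DataFrame
    pvalues: pd.DataFrame
    n_perm: int
    seed: int


def strength_adjust(result, n_perm: int = 1000, seed: int = 0) -> StrengthAdjustedResult:
    """Factor average strength out of the other weighted metrics.

    For each group size, each weighted metric is regressed on average strength
    across the composition-level values of both groups pooled; the residuals
    replace the values and the group difference is re-assessed by permuting
    group labels over the composition-level points.
    """
    values = result if isinstance(result, pd.DataFrame) else result.values
    w = values[values["mode"] == "weighted"]
    if "average_strength" not in set(w["metric"]):
        raise ParameterError("result lacks the average_strength metric")
    metrics = [m for m in w["metric"].unique()]
    if len(metrics) < 2:
        raise ParameterError("need at least one weighted metric besides strength")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    wide = w.pivot_table(
        index=["size", "composition", "group"], columns="metric", values="value"
    ).reset_index()

    adj_rows = []
    p_rows = []
    for size, block in wide.groupby("size"):
        x = block["average_strength"].to_numpy(dtype=float)
        is_ad = (block["group"] == "ad").to_numpy()
        if len(block) < 3:
            raise ParameterError(f"fewer than 3 points at size {size}")
        for m in metrics:
            y = block[m].to_numpy(dtype=float)
            if m == "average_strength":
                resid = y - y  # regression on itself: residuals are exactly zero
            else:
                slope, intercept = np.polyfit(x, y, 1)
                resid = y - (intercept + slope * x)
            for comp, grp, rv in zip(block["composition"], block["group"], resid):
                adj_rows.append(
                    {
                        "composition": comp,
                        "size": size,
                        "mode": "weighted",
                        "metric": m,
                        "group": grp,
                        "adjusted_value": rv,
                    }
                )
            obs = resid[is_ad].mean() - resid[~is_ad].mean()
            perm = np.empty(n_perm)
            for p in range(n_perm):
                flip = rng.permutation(is_ad)
                perm[p] = resid[flip].mean() - resid[~flip].mean()
            p_rows.append(
                {
                    "size": size,
                    "mode": "weighted",
                    "metric": m,
                    "observed": obs,
                    "pvalue": pvalue_plus_one(obs, perm),
                }
            )
    return StrengthAdjustedResult(
        adjusted=pd.DataFrame(adj_rows),
        pvalues=pd.DataFrame(p_rows),
        n_perm=n_perm,
        seed=seed,
    )
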