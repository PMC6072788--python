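"""Group-size / group-composition stability experiment for covariance networks.

For each of R random group compositions, nested subject subsets are grown from
a starting size (50 by default) in fixed steps (5 for binary, 10 for weighted
networks), structural covariance networks are rebuilt at every size, all graph
measures are recomputed, and a subject-level permutation test compares the AD
and control subgroups.  From the resulting traces the experiment derives:

* the minimum number of subjects (MNS) — the smallest group size from which
  the across-composition mean of a metric stays within +-5% of its full-group
  reference value for all larger sizes;
* the significance ratio — the fraction of compositions whose permutation
  test rejects at two-tailed p < 0.05;
* average binary adjacency matrices over many independent subsamples, whose
  entries estimate the probability that two regions are connected at a given
  group size.

All subsampling is without replacement; control and AD subsamples come from
disjoint pools, which makes the permutation tests between subgroups unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    adjacency_from_order,
    edge_count_at_density,
    edge_order,
    pearson_connectivity,
)
from .covariates import ResidualTable
from .exceptions import ParameterError
from .inference import (
    MetricSpec,
    evaluate_specs,
    permutation_stats,
    pvalue_plus_one,
)
from .metrics import BINARY_METRICS, WEIGHTED_METRICS

__all__ = [
    "SubsampleSchedule",
    "StabilityConfig",
    "StabilityResult",
    "AvgAdjacency",
    "MNSTable",
    "default_densities",
    "nested_subsample",
    "run_stability",
    "significance_ratio",
    "full_group_reference",
    "mns_from_trajectory",
    "compute_mns",
    "average_adjacency",
]

logger = logging.getLogger("covstab")


def default_densities() -> tuple[float, ...]:
    """The standard binary density sweep 0.05-0.35 in steps of 0.01."""
    return tuple(np.round(np.arange(5, 36), 2) / 100)


@dataclass(frozen=True)
class SubsampleSchedule:
    """Strictly increasing group sizes start, start+step, ..., <= max_size."""

    start: int = 50
    step: int = 5
    max_size: int = 290

    def __post_init__(self) -> None:
        if self.start < 3:
            raise ParameterError("schedule start must be >= 3")
        if self.step < 1:
            raise ParameterError("schedule step must be >= 1")
        if self.max_size < self.start:
            raise ParameterError("schedule max_size must be >= start")

    @property
    def sizes(self) -> list[int]:
        return list(range(self.start, self.max_size + 1, self.step))


@dataclass
class StabilityConfig:
    """Configuration of the subsampling experiment.

    Defaults mirror the full design: 100 compositions, binary sizes 50-290 in
    steps of 5 over densities 0.05-0.35, weighted sizes 50-290 in steps of 10,
    1000 permutations per test.
    """

    compositions: int = 100
    schedule_binary: SubsampleSchedule = field(
        default_factory=lambda: SubsampleSchedule(50, 5, 290)
    )
    schedule_weighted: SubsampleSchedule = field(
        default_factory=lambda: SubsampleSchedule(50, 10, 290)
    )
    densities: tuple[float, ...] = field(default_factory=default_densities)
    binary_metrics: tuple[str, ...] = BINARY_METRICS
    weighted_metrics: tuple[str, ...] = WEIGHTED_METRICS
    modes: tuple[str, ...] = ("binary", "weighted")
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if "char_path_length" in self.binary_metrics:
            raise ParameterError(
                "characteristic path length is not computed on binary graphs: "
                "they are generally disconnected at these densities"
            )
        for m in self.modes:
            if m not in ("binary", "weighted"):
                raise ParameterError(f"unknown mode {m!r}")
        for d in self.densities:
            if not 0.0 < d < 1.0:
                raise ParameterError("densities must lie in (0, 1)")
        if self.compositions < 1:
            raise ParameterError("compositions must be >= 1")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")

    def specs_for(self, mode: str) -> list[MetricSpec]:
        if mode == "binary":
            return [
                MetricSpec(m, "binary", d)
                for d in self.densities
                for m in self.binary_metrics
            ]
        return [MetricSpec(m, "weighted") for m in self.weighted_metrics]

    def all_sizes(self) -> list[int]:
        sizes: set[int] = set()
        if "binary" in self.modes:
            sizes.update(self.schedule_binary.sizes)
        if "weighted" in self.modes:
            sizes.update(self.schedule_weighted.sizes)
        return sorted(sizes)


@dataclass
class StabilityResult:
    """Tidy metric values and permutation p-values of the experiment.

    ``values``: composition, size, mode, density, metric, group, value.
    ``pvalues``: composition, size, mode, density, metric, pvalue.
    ``subsets``: per composition, the nested subject-id permutation per group
    (the subset of size s is the first s entries).
    """

    values: pd.DataFrame
    pvalues: pd.DataFrame
    config: StabilityConfig
    subsets: dict[int, dict[str, np.ndarray]]

    def to_csv(self, path) -> None:
        merged = self.values.merge(
            self.pvalues,
            on=["composition", "size", "mode", "density", "metric"],
            how="left",
        )
        merged.to_csv(path, index=False)


def nested_subsample(ids, schedule: SubsampleSchedule, seed) -> list[np.ndarray]:
    """Nested without-replacement subsets at each schedule size.

    One random permutation of the ids is truncated at each size, so the subset
    at size s is contained in the subset at every larger size.
    """
    ids = np.asarray(ids)
    if schedule.max_size > ids.size:
        raise ParameterError(
            f"schedule max_size {schedule.max_size} exceeds {ids.size} available ids"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    return [perm[:s] for s in schedule.sizes]


def _composition_rngs(seed: int, composition: int):
    sub = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(composition,)))
    perm = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(composition, 1))
    )
    return sub, perm


def run_stability(residuals: ResidualTable, config: StabilityConfig) -> StabilityResult:
    """Run the full nested-subsampling experiment on a residual table."""
    X_control = residuals.values("control")
    X_ad = residuals.values("ad")
    ids_control = residuals.ids("control")
    ids_ad = residuals.ids("ad")
    sizes = config.all_sizes()
    max_size = max(sizes)
    for name, X in (("control", X_control), ("ad", X_ad)):
        if X.shape[0] < max_size:
            raise ParameterError(
                f"group {name!r} has {X.shape[0]} subjects; schedule needs {max_size}"
            )

    bin_sizes = set(config.schedule_binary.sizes) if "binary" in config.modes else set()
    w_sizes = set(config.schedule_weighted.sizes) if "weighted" in config.modes else set()
    specs_by_size: dict[int, list[MetricSpec]] = {}
    for s in sizes:
        specs: list[MetricSpec] = []
        if s in bin_sizes:
            specs += config.specs_for("binary")
        if s in w_sizes:
            specs += config.specs_for("weighted")
        specs_by_size[s] = specs

    value_rows = []
    p_rows = []
    subsets: dict[int, dict[str, np.ndarray]] = {}
    for r in range(config.compositions):
        rng_sub, rng_perm = _composition_rngs(config.seed, r)
        perm_control = rng_sub.permutation(X_control.shape[0])
        perm_ad = rng_sub.permutation(X_ad.shape[0])
        subsets[r] = {
            "control": ids_control[perm_control[:max_size]],
            "ad": ids_ad[perm_ad[:max_size]],
        }
        for s in sizes:
            specs = specs_by_size[s]
            XA = X_ad[perm_ad[:s]]
            XC = X_control[perm_control[:s]]
            eval_fn = lambda X: evaluate_specs(X, specs)  # noqa: E731
            observed, perm_stats_ = permutation_stats(
                XA, XC, eval_fn, config.n_perm, rng_perm
            )
            val_ad = eval_fn(XA)
            val_control = val_ad - observed
            for i, spec in enumerate(specs):
                d = spec.density if spec.mode == "binary" else np.nan
                base = {
                    "composition": r,
                    "size": s,
                    "mode": spec.mode,
                    "density": d,
                    "metric": spec.metric,
                }
                value_rows.append({**base, "group": "control", "value": val_control[i]})
                value_rows.append({**base, "group": "ad", "value": val_ad[i]})
                p_rows.append(
                    {**base, "pvalue": pvalue_plus_one(observed[i], perm_stats_[:, i])}
                )
        logger.info("composition %d/%d done", r + 1, config.compositions)
    return StabilityResult(
        values=pd.DataFrame(value_rows),
        pvalues=pd.DataFrame(p_rows),
        config=config,
        subsets=subsets,
    )


def significance_ratio(result: StabilityResult, alpha: float = 0.05) -> pd.DataFrame:
    """Fraction of compositions with p < alpha per (size, mode, density, metric)."""
    p = result.pvalues if not isinstance(result, pd.DataFrame) else result
    out = (
        p.assign(significant=p["pvalue"] < alpha)
        .groupby(["size", "mode", "density", "metric"], dropna=False)["significant"]
        .mean()
        .rename("ratio")
        .reset_index()
    )
    return out


def full_group_reference(residuals: ResidualTable, config: StabilityConfig) -> pd.DataFrame:
    """Metric values computed from all available subjects per group.

    These are the stable reference values the MNS definition compares against.
    """
    specs: list[MetricSpec] = []
    for mode in config.modes:
        specs += config.specs_for(mode)
    rows = []
    for group in ("control", "ad"):
        X = residuals.values(group)
        vals = evaluate_specs(X, specs)
        for spec, v in zip(specs, vals):
            rows.append(
                {
                    "mode": spec.mode,
                    "density": spec.density if spec.mode == "binary" else np.nan,
                    "metric": spec.metric,
                    "group": group,
                    "reference": v,
                    "n_subjects": X.shape[0],
                }
            )
    return pd.DataFrame(rows)


def mns_from_trajectory(sizes, means, reference: float, tolerance: float = 0.05):
    """Smallest size from which the trajectory stays within the tolerance band.

    The band is reference +- tolerance * |reference|; the trajectory must stay
    inside it at the candidate size and every larger size (a later excursion
    disqualifies earlier entries).  Returns None when no size qualifies.
    """
    sizes = np.asarray(sizes)
    means = np.asarray(means, dtype=float)
    if sizes.size != means.size:
        raise ParameterError("sizes and means must have equal length")
    if reference == 0:
        raise ParameterError("reference value 0: relative tolerance undefined")
    order = np.argsort(sizes)
    sizes, means = sizes[order], means[order]
    within = np.abs(means - reference) <= tolerance * abs(reference)
    # suffix AND: qualifies iff within from here to the end
    ok = np.logical_and.accumulate(within[::-1])[::-1]
    idx = np.flatnonzero(ok)
    return int(sizes[idx[0]]) if idx.size else None


@dataclass
class MNSTable:
    """Minimum number of subjects per (metric, density-or-weighted, group)."""

    table: pd.DataFrame  # metric, mode, density, group, mns, reference, tolerance
    tolerance: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_mns(
    result: StabilityResult,
    reference: pd.DataFrame,
    tolerance: float = 0.05,
) -> MNSTable:
    """MNS per metric/density/group from across-composition mean trajectories."""
    values = result.values if not isinstance(result, pd.DataFrame) else result
    # a sentinel density for weighted rows keeps NaN out of the group keys
    values = values.assign(density=values["density"].fillna(-1.0))
    reference = reference.assign(density=reference["density"].fillna(-1.0))
    traj = (
        values.groupby(["mode", "density", "metric", "group", "size"])["value"]
        .mean()
        .reset_index()
    )
    ref_idx = reference.set_index(["mode", "density", "metric", "group"])
    rows = []
    for key, block in traj.groupby(["mode", "density", "metric", "group"]):
        try:
            ref = float(ref_idx.loc[key, "reference"])
        except KeyError:
            raise ParameterError(f"no full-group reference for {key}")
        mns = mns_from_trajectory(block["size"], block["value"], ref, tolerance)
        mode, density, metric, group = key
        rows.append(
            {
                "metric": metric,
                "mode": mode,
                "density": density if density >= 0 else np.nan,
                "group": group,
                "mns": mns,
                "reference": ref,
                "tolerance": tolerance,
            }
        )
    table = pd.DataFrame(rows).astype({"mns": "Int64"})
    return MNSTable(table=table, tolerance=tolerance)


@dataclass
class AvgAdjacency:
    """Mean of binary adjacency matrices over independent subsamples.

    Entry (i, j) estimates the probability that regions i and j are connected
    at the given group size and density.
    """

    matrix: np.ndarray
    group: str
    size: int
    density: float
    n_replicates: int
    region_labels: list[str]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.matrix, index=self.region_labels, columns=self.region_labels
        ).to_csv(path)


def average_adjacency(
    residuals: ResidualTable,
    group: str,
    size: int,
    n_replicates: int,
    density: float,
    seed: int = 0,
) -> AvgAdjacency:
    """Average binary adjacency over independent without-replacement subsamples."""
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if not 0.0 < density < 1.0:
        raise ParameterError("density must lie in (0, 1)")
    X = residuals.values(group)
    if size > X.shape[0]:
        raise ParameterError(
            f"size {size} exceeds the {X.shape[0]} subjects in group {group!r}"
        )
    n = X.shape[1]
    m = edge_count_at_density(density, n)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    acc = np.zeros((n, n))
    for _ in range(n_replicates):
        rows = rng.choice(X.shape[0], size=size, replace=False)
        r = pearson_connectivity(X[rows])
        i_sorted, j_sorted, _ = edge_order(r)
        acc += adjacency_from_order(i_sorted, j_sorted, m, n)
    return AvgAdjacency(
        matrix=acc / n_replicates,
        group=group,
        size=size,
        density=density,
        n_replicates=n_replicates,
        region_labels=residuals.region_labels,
    )
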