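"""Synthetic two-group cohorts of regional cortical measures.

The generator emulates a case/control morphometry study: each subject has a
vector of regional cortical thickness (mm) or volume (mm^3) values that are
linear in age, sex and (for volumes) intracranial volume, plus a group-specific
latent shared-atrophy factor.  The factor induces a uniform pairwise Pearson
correlation between regions within a group,

    rho_g = lambda_g^2 / (lambda_g^2 + sigma^2),

where ``lambda_g`` is the group's factor loading and ``sigma`` the residual
standard deviation.  Giving the disease group a larger loading reproduces the
empirical observation that inter-regional correlations of atrophy are stronger
in Alzheimer's disease than in elderly controls, which is the phenomenon the
stability analysis probes.  The closed form above serves as the analytic
ground truth for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "CohortParams",
    "SubjectTable",
    "generate_cohort",
    "analytic_strength",
    "equalize_groups",
]

CONTROL = "control"
AD = "ad"
GROUPS = (CONTROL, AD)

#: Non-region columns of a subject table, in canonical order.
META_COLUMNS = ["subject_id", "group", "age", "sex", "icv"]


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults describe a cortical-thickness study of elderly AD patients and
    controls: mean thickness ~2.5 mm with ~0.15 mm residual spread, mild
    age-related thinning, a global AD thinning offset, and latent-factor
    loadings giving within-group inter-regional correlations of roughly 0.26
    (controls) and 0.39 (AD).
    """

    n_per_group: int = 293
    n_regions: int = 68
    loading_control: float = 0.09
    loading_ad: float = 0.12
    noise_sd: float = 0.15
    region_mean: float = 2.5
    ad_mean_offset: float = 0.15
    beta_age: float = -0.008
    beta_sex: float = 0.05
    beta_icv: float = 0.0
    age_mean: float = 75.0
    age_sd: float = 6.0
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    female_ratio: float = 0.5
    measure_kind: str = "thickness"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if self.n_regions < 3:
            raise ParameterError("n_regions must be >= 3")
        if not self.noise_sd > 0:
            raise ParameterError("noise_sd must be > 0")
        if self.loading_control < 0:
            raise ParameterError("loading_control must be >= 0")
        if self.loading_ad < 0:
            raise ParameterError("loading_ad must be >= 0")
        if self.ad_mean_offset < 0:
            raise ParameterError("ad_mean_offset must be >= 0")
        if self.age_sd < 0:
            raise ParameterError("age_sd must be >= 0")
        if self.icv_sd < 0:
            raise ParameterError("icv_sd must be >= 0")
        if not 0.0 <= self.female_ratio <= 1.0:
            raise ParameterError("female_ratio must lie in [0, 1]")
        if self.measure_kind not in ("thickness", "volume"):
            raise ParameterError("measure_kind must be 'thickness' or 'volume'")

    def loading(self, group: str) -> float:
        if group == CONTROL:
            return self.loading_control
        if group == AD:
            return self.loading_ad
        raise ParameterError(f"unknown group label {group!r}")

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_region_labels(n_regions: int) -> list[str]:
    """Placeholder region names R001...Rnnn (real atlas names pass through)."""
    return [f"R{i + 1:03d}" for i in range(n_regions)]


@dataclass
class SubjectTable:
    """Subjects x (covariates + regional measures), the pipeline's raw input.

    ``data`` holds one row per subject with columns ``subject_id, group, age,
    sex, icv`` followed by one column per region.  ``sex`` is coded 0/1
    (1 = female by the generator's convention).
    """

    data: pd.DataFrame
    measure_kind: str = "thickness"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParameterError(f"subject table lacks columns {missing}")
        if self.data["subject_id"].duplicated().any():
            raise ParameterError("duplicate subject_id in subject table")
        if self.data[self.region_labels].isna().any().any():
            raise ParameterError("missing regional measures in subject table")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ParameterError(f"unknown group labels {sorted(bad)}")

    @property
    def region_labels(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def measures(self, group: str | None = None) -> np.ndarray:
        """Regional measures as a subjects x regions float array."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df[self.region_labels].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        # %.17g round-trips any float64 exactly
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, measure_kind: str = "thickness") -> "SubjectTable":
        return cls(
            pd.read_csv(path, float_precision="round_trip"), measure_kind=measure_kind
        )


def analytic_strength(params: CohortParams, group: str) -> float:
    """Expected within-group off-diagonal Pearson correlation.

    Under the single-factor model with loading ``lambda_g`` and residual SD
    ``sigma``, every region pair has correlation lambda_g^2/(lambda_g^2+sigma^2)
    once covariate effects are removed.
    """
    lam = params.loading(group)
    return lam**2 / (lam**2 + params.noise_sd**2)


def generate_cohort(params: CohortParams) -> SubjectTable:
    """Draw a two-group cohort from the latent-factor model.

    For subject i in group g and region r,

        y_ir = mu_r - 1{g=ad} * delta
               + beta_age * (age_i - age_mean) + beta_sex * sex_i
               + 1{volume} * beta_icv * (icv_i - icv_mean)
               + lambda_g * f_i + eps_ir,

    with f_i ~ N(0,1) and eps_ir ~ N(0, sigma^2) independent.  Covariates,
    factor scores and noise use independent substreams of the master seed, so
    each stage is reproducible on its own.
    """
    n, R = params.n_per_group, params.n_regions
    ss = np.random.SeedSequence(params.seed)
    cov_rng, factor_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    total = 2 * n
    age = cov_rng.normal(params.age_mean, params.age_sd, size=total)
    sex = (cov_rng.random(total) < params.female_ratio).astype(int)
    icv = cov_rng.normal(params.icv_mean, params.icv_sd, size=total)
    factor = factor_rng.standard_normal(total)
    noise = noise_rng.normal(0.0, params.noise_sd, size=(total, R))

    group = np.repeat([CONTROL, AD], n)
    loading = np.where(group == AD, params.loading_ad, params.loading_control)
    offset = np.where(group == AD, -params.ad_mean_offset, 0.0)

    base = (
        params.region_mean
        + offset
        + params.beta_age * (age - params.age_mean)
        + params.beta_sex * sex
    )
    if params.measure_kind == "volume":
        base = base + params.beta_icv * (icv - params.icv_mean)
    measures = base[:, None] + (loading * factor)[:, None] + noise

    labels = default_region_labels(R)
    data = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(total)],
            "group": group,
            "age": age,
            "sex": sex,
            "icv": icv,
        }
    )
    data = pd.concat([data, pd.DataFrame(measures, columns=labels)], axis=1)
    return SubjectTable(data, measure_kind=params.measure_kind)


def equalize_groups(table: SubjectTable, seed: int) -> SubjectTable:
    """Randomly discard subjects from the larger group to equalize sizes.

    The larger group is subsampled without replacement down to the smaller
    group's size; the smaller group is untouched and row order is preserved.
    Deterministic for a given seed.
    """
    sizes = table.group_sizes()
    for g, s in sizes.items():
        if s == 0:
            raise ParameterError(f"group {g!r} is empty")
    if sizes[CONTROL] == sizes[AD]:
        return SubjectTable(table.data.copy(), measure_kind=table.measure_kind)

    larger = CONTROL if sizes[CONTROL] > sizes[AD] else AD
    target = min(sizes.values())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mask = table.data["group"].to_numpy() == larger
    idx = np.flatnonzero(mask)
    keep = rng.choice(idx, size=target, replace=False)
    drop = np.setdiff1d(idx, keep)
    kept = table.data.drop(index=table.data.index[drop]).reset_index(drop=True)
    return SubjectTable(kept, measure_kind=table.measure_kind)
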