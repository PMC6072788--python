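import numpy as np
import pandas as pd
import pytest

from covstab import CohortParams, apply_residualization, fit_covariate_model, generate_cohort
from covstab.covariates import ResidualTable


def residual_table_from_arrays(X_control, X_ad, region_labels=None):
    """Build a ResidualTable directly from per-group residual arrays."""
    X_control = np.asarray(X_control, dtype=float)
    X_ad = np.asarray(X_ad, dtype=float)
    n_regions = X_control.shape[1]
    labels = region_labels or [f"R{i + 1:03d}" for i in range(n_regions)]
    n_c, n_a = X_control.shape[0], X_ad.shape[0]
    data = pd.DataFrame(
        {
            "subject_id": [f"C{i:04d}" for i in range(n_c)]
            + [f"A{i:04d}" for i in range(n_a)],
            "group": ["control"] * n_c + ["ad"] * n_a,
        }
    )
    resid = pd.DataFrame(np.vstack([X_control, X_ad]), columns=labels)
    return ResidualTable(
        pd.concat([data, resid], axis=1), measure_kind="thickness", covariates=["age", "sex"]
    )


@pytest.fixture(scope="session")
def small_params():
    return CohortParams(n_per_group=80, n_regions=20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    model = fit_covariate_model(small_cohort)
    return apply_residualization(model, small_cohort)
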