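import numpy as np
import pandas as pd
import pytest

from neuroreserve import (
    CohortConfig,
    build_template_graph,
    default_scheme,
    generate_cohort,
    generate_outcome_and_volumes,
    genfi_truth,
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template_graph(scheme):
    return build_template_graph(scheme)


@pytest.fixture(scope="session")
def cohort():
    """One seeded default-size cohort."""
    return generate_cohort(CohortConfig(), seed=3)


@pytest.fixture(scope="session")
def cohort_with_outcome(cohort):
    """Cohort, latent composite and raw volumes at the default truth values."""
    truth = genfi_truth()
    latent, volumes = generate_outcome_and_volumes(cohort, truth, seed=4)
    return cohort.assign(latent=latent.to_numpy()), volumes, truth


@pytest.fixture()
def small_volume_table(scheme):
    """Three subjects with hand-set TIV and region volumes."""
    rng = np.random.default_rng(11)
    rows = []
    for i, tiv in enumerate([1_400_000.0, 1_500_000.0, 1_350_000.0]):
        row = {"subject_id": f"P{i + 1:04d}", "tiv": tiv}
        for name in scheme.names:
            row[name] = float(rng.uniform(1_000, 90_000))
        rows.append(row)
    return pd.DataFrame(rows)
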