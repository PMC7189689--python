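import numpy as np
import pandas as pd
import pytest

from xcimeth import CELL_TYPES, MethylationCohort


def make_cohort(
    beta: np.ndarray,
    sexes,
    ages=None,
    pair_ids=None,
    detection_p=None,
    probe_flags=None,
    label="test",
) -> MethylationCohort:
    """Assemble a cohort from raw arrays with sensible metadata defaults."""
    n_probes, n_samples = beta.shape
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    probe_ids = [f"cg{i:05d}" for i in range(n_probes)]
    if ages is None:
        ages = np.linspace(60, 80, n_samples)
    if pair_ids is None:
        pair_ids = sample_ids  # singletons
    cells = np.full((n_samples, 6), 1 / 6)
    samples = pd.DataFrame({
        "sex": list(sexes), "age": ages, "twin_pair_id": list(pair_ids),
        "zygosity": "NA", "sentrix_id": "chip0", "sentrix_position": "R01C01",
        **{ct: cells[:, i] for i, ct in enumerate(CELL_TYPES)},
    }, index=pd.Index(sample_ids, name="sample_id"))
    cross = np.zeros(n_probes, bool)
    poly = np.zeros(n_probes, bool)
    if probe_flags is not None:
        cross, poly = probe_flags
    probes = pd.DataFrame({
        "chromosome": "X",
        "position": np.arange(n_probes) * 1000 + 1,
        "gene_region": "Body",
        "is_cross_reactive": cross,
        "is_polymorphic": poly,
    }, index=pd.Index(probe_ids, name="probe_id"))
    pidx = pd.Index(probe_ids, name="probe_id")
    detp = None
    if detection_p is not None:
        detp = pd.DataFrame(detection_p, index=pidx, columns=sample_ids)
    return MethylationCohort(
        beta=pd.DataFrame(beta, index=pidx, columns=sample_ids),
        samples=samples, probes=probes, detection_p=detp, cohort_label=label,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)
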