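import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from florthograph import simulate


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by unit tests (fast to generate and
    to align: short proteins, few genes)."""
    cfg = simulate.SimulationConfig(
        seed=11,
        n_reference_genes=20,
        n_decoys=8,
        protein_length_mean=220.0,
    )
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """Ortholog pipeline result on the small study."""
    from florthograph import orthology

    study = small_study
    return orthology.run_pipeline(
        study.reference.genes,
        {study.hexaploid.label: study.hexaploid.sequences,
         study.diploid.label: study.diploid.sequences},
        reference_species=study.config.reference_species,
    )
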