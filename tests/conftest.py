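import numpy as np
import pandas as pd
import pytest

from trophostab import (
    KingdomCountTable,
    SampleMetadata,
    TraitFrequencyTable,
    generate_field_study,
)
from trophostab.stats_report import run_field_pipeline, run_microcosm_pipeline

STUDY_SEED = 1


@pytest.fixture(scope="session")
def field_study():
    """One complete synthetic field study shared across tests."""
    return generate_field_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def field_bundle(tmp_path_factory):
    """A full field-pipeline run (with file outputs) shared across tests."""
    out = tmp_path_factory.mktemp("field_run")
    return run_field_pipeline(out_dir=out, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def microcosm_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("microcosm_run")
    return run_microcosm_pipeline(out_dir=out, seed=STUDY_SEED)


@pytest.fixture
def tiny_counts():
    """A hand-written 3 OTU x 4 sample bacterial count table."""
    df = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 7], [2, 2, 2, 2]],
        index=["OTU1", "OTU2", "OTU3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return KingdomCountTable(kingdom="bacteria", counts=df)


@pytest.fixture
def tiny_meta():
    return [
        SampleMetadata("s1", "FQ", "C", 1),
        SampleMetadata("s2", "FQ", "NK", 1),
        SampleMetadata("s3", "FQ", "NPK", 1),
        SampleMetadata("s4", "FQ", "NPKM", 1),
    ]


@pytest.fixture
def tiny_traits():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]],
        index=["geneA", "geneB"],
        columns=["s1", "s2", "s3"],
    )
    return TraitFrequencyTable(frequencies=df)


def random_abundance_table(n_otus, n_samples, seed, kingdoms=None):
    """Independent lognormal abundance table (no planted correlation)."""
    from trophostab import IntegratedAbundanceTable, KINGDOMS

    rng = np.random.default_rng(seed)
    values = rng.lognormal(0.0, 1.0, size=(n_otus, n_samples))
    otus = [f"o{i}" for i in range(n_otus)]
    if kingdoms is None:
        kingdoms = [KINGDOMS[i % 4] for i in range(n_otus)]
    abund = pd.DataFrame(values, index=otus,
                         columns=[f"s{j}" for j in range(n_samples)])
    abund = abund / abund.sum(axis=0)
    return IntegratedAbundanceTable(
        abundances=abund, kingdoms=pd.Series(kingdoms, index=otus))
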