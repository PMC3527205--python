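import dataclasses

import pandas as pd
import pytest

from painexome.synthetic_data import (
    SimConfig,
    simulate_regulatory_network,
    simulate_study,
    write_fixture_bundle,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but complete two-cohort study configuration."""
    return dataclasses.replace(
        SimConfig(),
        n_genes=40,
        n_subjects_per_cohort=((30, 30), (30, 30)),
        sites_per_gene=(8, 16),
        n_planted_genes=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_network(small_config):
    return simulate_regulatory_network(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_study, tmp_path_factory):
    dest = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(small_study, dest)
    return dest, paths


def cohort_labels(study, cohort: str) -> pd.Series:
    """Binary labels (1 = insensitive) for one cohort's sequenced subjects."""
    sub = study.subjects[(study.subjects["cohort"] == cohort) & study.subjects["sequenced"]]
    return sub.set_index("id")["label"].map({"sensitive": 0, "insensitive": 1})


@pytest.fixture(scope="session")
def cohort1_labels(small_study):
    return cohort_labels(small_study, "cohort1")
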