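import dataclasses

import pytest

from ssfaers.synthetic_data import (
    DEFAULT_ROSTER,
    GeneratorConfig,
    generate_reports,
    write_faers_ascii,
)


@pytest.fixture(scope="session")
def small_config():
    """Small-but-realistic study conditions shared by plumbing tests."""
    return GeneratorConfig(n_reports_per_quarter=1250, quarters=("2024Q1", "2024Q2"), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    quarters, truth = generate_reports(small_config)
    return quarters, truth


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    quarters, truth = small_dataset
    out = tmp_path_factory.mktemp("faers")
    write_faers_ascii(quarters, out)
    return out


def null_roster():
    """The default roster with every planted rate ratio reset to 1."""
    return tuple(dataclasses.replace(spec, lam=1.0) for spec in DEFAULT_ROSTER)
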