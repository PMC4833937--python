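import pathlib

import pytest

from glyfam.synthetic_data import (
    SimConfig,
    generate_expression,
    generate_genome,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One synthetic genome bundle shared across the suite."""
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def bundle_dir(dataset, sim_config, tmp_path_factory) -> pathlib.Path:
    """The dataset written out in the pipeline's input formats."""
    d = tmp_path_factory.mktemp("bundle")
    dataset.write(d)
    tissue, classes, stress, _ = generate_expression(sim_config)
    tissue.to_csv(d / "tissue.tsv", sep="\t")
    stress.to_csv(d / "stress.tsv", sep="\t")
    with open(d / "classes.tsv", "w") as fh:
        fh.write("condition\tclass\n")
        for cond, cls in classes.items():
            fh.write(f"{cond}\t{cls}\n")
    return d
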