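import numpy as np
import pytest

from sbgturnover.datasets import classification_benchmark, turnover_benchmark
from sbgturnover.io_formats import (
    write_expression,
    write_orthogroups,
    write_species_meta,
)
from sbgturnover.pipeline import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def benchmark_full():
    return classification_benchmark()


@pytest.fixture(scope="session")
def benchmark_turnover():
    return turnover_benchmark()


def write_benchmark(dataset, directory):
    """Materialize an in-memory benchmark dataset as pipeline inputs."""
    write_orthogroups(
        dataset.orthogroups,
        directory / "orthogroups.tsv",
        species_order=list(dataset.species_meta),
    )
    write_expression(dataset.expression, directory / "expression.tsv")
    write_species_meta(dataset.species_meta, directory / "species_meta.tsv")
    return PipelineConfig(
        orthogroups=str(directory / "orthogroups.tsv"),
        expression=str(directory / "expression.tsv"),
        species_meta=str(directory / "species_meta.tsv"),
        out_dir=str(directory / "reports"),
    )
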