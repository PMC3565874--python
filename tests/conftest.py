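"""Shared fixtures: one seeded synthetic dataset and one pipeline run."""

from dataclasses import dataclass

import pytest

from retrointron.core import Genome
from retrointron.io import read_annotation, read_bed12
from retrointron.report import PipelineReport, run_pipeline
from retrointron.simulate import (
    SimulationConfig,
    SimulatedDataset,
    simulate_dataset,
    write_dataset,
)

FIXTURE_SEED = 11


@dataclass
class LoadedDataset:
    dataset: SimulatedDataset
    paths: dict
    genome: Genome
    genes: dict
    parents: dict
    transcripts: list


def _load(tmpdir, config=None, seed=FIXTURE_SEED) -> LoadedDataset:
    ds = simulate_dataset(config or SimulationConfig(), seed)
    paths = write_dataset(ds, str(tmpdir))
    genome = Genome(paths["genome"])
    genes = read_annotation(paths["annotation"])
    parents = {gid: g for gid, g in genes.items() if gid.startswith("parent")}
    transcripts = read_bed12(paths["transcripts"])
    return LoadedDataset(ds, paths, genome, genes, parents, transcripts)


@pytest.fixture(scope="session")
def fixture_data(tmp_path_factory) -> LoadedDataset:
    """Default-condition synthetic dataset, written to disk and re-read
    through the standard-format readers."""
    return _load(tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def pipeline_report(fixture_data) -> PipelineReport:
    """Full pipeline run on the shared fixture."""
    return run_pipeline(
        fixture_data.genome, fixture_data.parents, fixture_data.genes,
        transcripts=fixture_data.transcripts,
        repeats=fixture_data.dataset.repeats,
    )


@pytest.fixture(scope="session")
def clean_fixture_data(tmp_path_factory) -> LoadedDataset:
    """Zero-divergence variant of the shared fixture."""
    cfg = SimulationConfig(sub_rate=0.0, indel_rate=0.0)
    return _load(tmp_path_factory.mktemp("fixture0"), cfg)
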