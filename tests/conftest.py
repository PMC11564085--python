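"""Shared fixtures: synthetic worlds and pipeline runs reused across the suite."""

from __future__ import annotations

from pathlib import Path

import pytest

from evam.pipeline import ScenarioConfig, run_pipeline, run_sensitivity_suite
from evam.synthetic import WorldConfig, generate_world

WORLD_SEED = 1234


def make_config(world_dir: Path, out_dir: Path, **overrides) -> ScenarioConfig:
    base = dict(
        mortality=str(world_dir / "mortality.csv"),
        population=str(world_dir / "population.csv"),
        income=str(world_dir / "income.csv"),
        income_growth=str(world_dir / "income_growth.csv"),
        metadata=str(world_dir / "country_metadata.csv"),
        out_dir=str(out_dir),
        log_level="WARNING",
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def default_world():
    """The reference noisy world (study conditions)."""
    return generate_world(WorldConfig(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def default_world_dir(default_world, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("world_default")
    default_world.write_csvs(d)
    return d


@pytest.fixture(scope="session")
def noiseless_world_config():
    return WorldConfig(seed=WORLD_SEED, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_world_dir(noiseless_world_config, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("world_noiseless")
    generate_world(noiseless_world_config).write_csvs(d)
    return d


@pytest.fixture(scope="session")
def base_artifacts(default_world_dir, tmp_path_factory):
    """Full base-case pipeline run on the reference noisy world."""
    out = tmp_path_factory.mktemp("run_base")
    cfg = make_config(default_world_dir, out)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def sensitivity_table(default_world_dir, tmp_path_factory):
    """7-scenario sensitivity suite on the reference noisy world."""
    out = tmp_path_factory.mktemp("suite")
    cfg = make_config(default_world_dir, out)
    return run_sensitivity_suite(cfg)
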