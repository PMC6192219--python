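import numpy as np
import pandas as pd
import pytest

from epiclockbench import (
    IntensityData,
    Manifest,
    SimulationConfig,
    simulate_cohort,
    simulate_intensities,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: full clock sizes, few subjects/invariant probes."""
    return SimulationConfig(n_subjects=40, n_invariant_cpgs=60, replicate_pairs=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_intensities(small_config, small_cohort):
    _, truth = small_cohort
    return simulate_intensities(truth, small_config, "A")


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SimulationConfig(
        n_subjects=50, n_invariant_cpgs=30, beta_noise_sd=0.0, replicate_pairs=0, seed=7
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def tiny_manifest() -> Manifest:
    table = pd.DataFrame(
        {
            "probe_id": ["cg01", "cg02", "cg03", "rs01"],
            "design_type": ["I", "II", "II", "II"],
            "color_channel": ["Grn", "Both", "Both", "Both"],
            "probe_class": ["cg", "cg", "cg", "rs"],
        }
    ).set_index("probe_id")
    return Manifest(table, platform="tiny")


def make_intensities(meth: dict, unmeth: dict, manifest=None) -> IntensityData:
    """Build a bare IntensityData from {probe: [per-sample values]} dicts."""
    probes = list(meth)
    samples = [f"s{i}" for i in range(len(next(iter(meth.values()))))]
    m = pd.DataFrame.from_dict(meth, orient="index", columns=samples).astype(float)
    u = pd.DataFrame.from_dict(unmeth, orient="index", columns=samples).astype(float)
    m.index = pd.Index(probes, name="probe_id")
    u.index = m.index
    return IntensityData(methylated=m, unmethylated=u, manifest=manifest)
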