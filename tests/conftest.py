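import numpy as np
import pytest

from laminardyn.design import DesignSpec
from laminardyn.synthetic import EffectSpec, NoiseSpec, simulate_subject


@pytest.fixture(scope="session")
def design_spec() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def load_only_spec() -> DesignSpec:
    return DesignSpec(n_runs_load=2, n_runs_motor=0)


@pytest.fixture(scope="session")
def small_subject(load_only_spec):
    """One simulated subject, load runs only, small voxel count."""
    effects = EffectSpec(
        amplitudes={("superficial", "high", "delay"): 0.3},
        pattern_amplitudes={
            ("superficial", c, p): 0.5
            for c in ("high", "low")
            for p in ("encoding", "delay", "retrieval")
        },
        pattern_dynamics="stable",
    )
    return simulate_subject(
        load_only_spec, effects, NoiseSpec(), n_voxels_per_layer=24, seed=42
    )
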