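import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_beat():
    from ecgrepol import synth

    return synth.baseline_beat_params()


@pytest.fixture(scope="session")
def pk_models():
    from ecgrepol import synth

    return synth.default_pk_models()


@pytest.fixture(scope="session")
def clean_recording(baseline_beat):
    """Noiseless, jitter-free 10-s recording with ground truth."""
    from ecgrepol import synth

    return synth.synthesize_recording(
        baseline_beat, noise_uv_rms=0.0, rr_variability=0.0, seed=0
    )


@pytest.fixture(scope="session")
def noisy_recording(baseline_beat):
    from ecgrepol import synth

    return synth.synthesize_recording(
        baseline_beat, noise_uv_rms=12.0, rr_variability=0.02, seed=1
    )


@pytest.fixture(scope="session")
def small_trial_table():
    """Biomarker-level table for a reduced crossover (fast, shared)."""
    from ecgrepol import synth

    design = synth.TrialDesign(
        n_subjects=10,
        n_female=4,
        arms=("placebo", "dofetilide", "mexiletine+dofetilide"),
        timepoint_hours=(6.5, 13.0),
        replicates_per_timepoint=2,
        seed=123,
    )
    return synth.simulate_biomarker_trial(design)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
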