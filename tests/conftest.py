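import pandas as pd
import pytest

from meripairray import GroupDesign, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy experiment with planted effects (default conditions)."""
    cfg = SimulationConfig(
        n_mrna=200,
        n_lncrna=50,
        planted={"hyper-up": 20, "hypo-down": 20, "hyper-only": 10, "up-only": 10},
        seed=42,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free experiment with strong planted effects (exact recovery)."""
    cfg = SimulationConfig(
        n_mrna=150,
        n_lncrna=50,
        planted={"hyper-up": 15, "hypo-down": 15, "hyper-only": 10, "up-only": 10},
        meth_effect_log2=3.0,
        noise_sd_log2=0.0,
        array_scale_sd_log2=0.0,
        seed=7,
    )
    return simulate_experiment(cfg)


@pytest.fixture()
def design6():
    return GroupDesign(
        {
            "sham_1": "sham",
            "sham_2": "sham",
            "sham_3": "sham",
            "sci_1": "sci",
            "sci_2": "sci",
            "sci_3": "sci",
        }
    )


def intensity_frame(rows):
    """Build a probe-intensity frame from (probe, transcript, sample, channel,
    intensity, spike) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "transcript_id",
            "sample_id",
            "channel",
            "intensity",
            "is_spike_in",
        ],
    )
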