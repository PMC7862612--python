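import pytest

from leukotox import EffectParameters, ExperimentDesign


@pytest.fixture
def design6():
    """Six fish, full scenario grid, three tested concentrations."""
    return ExperimentDesign(fish_ids=tuple(f"F{i}" for i in range(1, 7)),
                            concentrations=(0.0, 1.0, 5.0, 10.0),
                            n_technical=3, endpoint="phagocytosis")


@pytest.fixture
def rich_params():
    """Non-trivial generating coefficients for recovery checks."""
    return EffectParameters(
        intercept=2.0,
        fish_effects={"F2": 0.3, "F3": -0.2, "F4": 0.1, "F5": 0.5,
                      "F6": -0.4},
        time_effect=0.8, lps_effect=1.2,
        conc_effects={1.0: -0.1, 5.0: -0.5, 10.0: -1.0},
        time_lps_interaction=0.4,
        time_conc_interactions={1.0: -0.05, 5.0: -0.15, 10.0: -0.3},
        lps_conc_interactions={1.0: 0.05, 5.0: -0.2, 10.0: -0.45},
        residual_sd=1.0, technical_sd=0.5)


@pytest.fixture
def noise_free(rich_params):
    from dataclasses import replace
    return replace(rich_params, residual_sd=0.0, technical_sd=0.0)
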