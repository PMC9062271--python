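import math

import pytest

from savanna_agb.calibration import CalibrationModels
from savanna_agb.inventory import (
    DamageAssessment,
    StemMeasure,
    WoodyIndividual,
)
from savanna_agb.synthetic_data import (
    SimulationConfig,
    simulate_study,
    zero_noise_config,
)


@pytest.fixture(scope="session")
def paper_models():
    return CalibrationModels.paper_defaults()


@pytest.fixture(scope="session")
def noisy_study():
    """Default 60-plot study with measurement noise, fixed seed."""
    return simulate_study(SimulationConfig(
        seed=11, noise_height=0.08, noise_circ=0.03,
        noise_cd=0.08, noise_wood=0.05,
    ))


@pytest.fixture(scope="session")
def clean_study():
    """Default 60-plot study with all measurement noise off."""
    return simulate_study(zero_noise_config(seed=7))


def make_adult(
    circ130=None, basal=None, alt=None, height=900.0, loss=None,
    dead=(), species="Burkea africana", cd=None, individual_id="T1",
):
    """Compact builder for a single-plot adult/gulliver test individual.

    ``dead`` is a sequence of (basal_circ, topkill_agents) pairs; ``alt``
    is an (alt_circ, alt_height) pair on the living stem.
    """
    stems = []
    if circ130 or basal or alt:
        stems.append(StemMeasure(
            basal_circ_cm=basal,
            circ130_cm=circ130,
            alt_circ_cm=alt[0] if alt else None,
            alt_height_cm=alt[1] if alt else None,
        ))
    for basal_dead, agents in dead:
        stems.append(StemMeasure(
            basal_circ_cm=basal_dead, is_dead=True,
            topkill_agents=tuple(agents),
        ))
    return WoodyIndividual(
        individual_id=individual_id, plot_id="P001", species=species,
        height_cm=height,
        crown_diameter_1_m=cd, crown_diameter_2_m=cd,
        stems=stems,
        damage=DamageAssessment(loss_percent_by_agent=loss or {}),
    )


def make_subadult(height=120.0, cd=0.8, loss=None, individual_id="S1",
                  species="Ochna pulchra"):
    return WoodyIndividual(
        individual_id=individual_id, plot_id="P001", species=species,
        height_cm=height, crown_diameter_1_m=cd, crown_diameter_2_m=cd,
        damage=DamageAssessment(loss_percent_by_agent=loss or {}),
    )


def circ_of_dbh(dbh):
    return math.pi * dbh
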