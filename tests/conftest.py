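import numpy as np
import pytest

import distcapture as dc
from distcapture.observer import ExperimentDesign


@pytest.fixture(scope="session")
def design():
    return dc.default_design()


@pytest.fixture(scope="session")
def observer():
    return dc.ObserverParams(seed=3)


@pytest.fixture(scope="session")
def responses(design, observer):
    return dc.simulate_coincidence_responses(design, observer)


@pytest.fixture(scope="session")
def judgments(design, observer):
    return dc.simulate_absolute_judgments(design, observer)


@pytest.fixture(scope="session")
def true_power_fits(observer):
    """Power-law fits equal to the generating observer's distance functions."""
    aud = dc.PowerFit(k=observer.k_aud, a=observer.a_aud, r_squared=1.0, modality="aud")
    vis = dc.PowerFit(k=observer.k_vis, a=observer.a_vis, r_squared=1.0, modality="vis")
    return aud, vis


@pytest.fixture(scope="session")
def pooled_curves(responses):
    return dc.dprime_curves(responses, pooled=True)


def one_block_design(visual_m, grid, trials=30, n_subjects=11):
    return ExperimentDesign(
        visual_targets=(float(visual_m),),
        auditory_grids=(tuple(float(g) for g in grid),),
        trials_per_stimulus=trials,
        n_subjects=n_subjects,
        absolute_auditory_distances=(1.0, 2.0),
        absolute_visual_distances=(1.0,),
    )


def log_sd_diff(params):
    """Log-space SD of the percept difference A - V."""
    return float(
        np.sqrt(
            params.s_aud ** 2
            + params.s_vis ** 2
            - 2.0 * params.r * params.s_aud * params.s_vis
        )
    )
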