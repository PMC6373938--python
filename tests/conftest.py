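import numpy as np
import pytest

from premcal.banks import equip_ph_bank
from premcal.data_io import Item, ItemBank, ResponseMatrix
from premcal.pcm import PCMModel, fit_pcm
from premcal.synthetic import SimulationDesign, simulate_responses


@pytest.fixture(scope="session")
def published_bank() -> ItemBank:
    return equip_ph_bank()


@pytest.fixture(scope="session")
def published_model(published_bank) -> PCMModel:
    """The printed bank wrapped as a model on the standard-normal metric."""
    return PCMModel.from_bank(published_bank)


@pytest.fixture(scope="session")
def toy_bank() -> ItemBank:
    """Three 3-category items with well-separated thresholds."""
    return ItemBank(
        [
            Item("a", "", (-1.5, 0.0), (0, 1, 2)),
            Item("b", "", (-0.5, 1.0), (0, 1, 2)),
            Item("c", "", (0.5, 2.0), (0, 1, 2)),
        ]
    )


@pytest.fixture(scope="session")
def clean_study_matrix(published_bank):
    """Clean (pathology-free) responses from the printed bank at study spread."""
    design = SimulationDesign(
        bank=published_bank,
        n_persons=500,
        theta_mean=-0.08,
        theta_sd=1.9,
        missing_rate=0.0,
        seed=314,
    )
    matrix, theta = simulate_responses(design)
    return matrix, theta


@pytest.fixture(scope="session")
def fitted_clean_model(clean_study_matrix) -> PCMModel:
    matrix, _ = clean_study_matrix
    return fit_pcm(matrix)


def make_matrix(responses, max_cat=None, group=None) -> ResponseMatrix:
    responses = np.asarray(responses, dtype=float)
    n, k = responses.shape
    if max_cat is None:
        with np.errstate(all="ignore"):
            max_cat = np.maximum(np.nanmax(np.where(np.isnan(responses), 0, responses), axis=0), 1)
    elif np.isscalar(max_cat):
        max_cat = np.full(k, max_cat)
    return ResponseMatrix(
        responses,
        [f"p{i}" for i in range(n)],
        [f"i{j}" for j in range(k)],
        np.asarray(max_cat, dtype=int),
        group,
    )
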