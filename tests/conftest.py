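import numpy as np
import pytest

import flyniche as fn
from flyniche.landscape import _eligible_cells, true_suitability
from flyniche.maxent import fit_maxent, predict_over_mask, sample_background
from flyniche.occurrences import extract_env_at_points


@pytest.fixture(scope="session")
def stack64():
    """Smooth 64x64 landscape with 5 env layers and a 0.95-correlated pair."""
    return fn.generate_landscape(64, 64, 5, 8, 0.95, 42)


@pytest.fixture(scope="session")
def small_stack():
    """Flat-noise 20x20 stack for cheap geometric tests."""
    return fn.generate_landscape(20, 20, 3, 2, None, 7)


def occurrences_at_cells(stack, cells, species="test_species"):
    """Occurrence set placed at the centers of given (row, col) cells."""
    records = []
    for i, (r, c) in enumerate(cells):
        lon, lat = stack.cell_center(r, c)
        records.append((f"r{i}", float(lon), float(lat)))
    return fn.OccurrenceSet(species=species, records=records)


@pytest.fixture(scope="session")
def recovery_experiment():
    """Synthetic parameter-recovery setup: 200 presences, 5 layers, one
    informative (env_1), fixed seeds; fitted LQ model at rm = 1."""
    stack = fn.generate_landscape(60, 60, 5, 8, None, 11)
    truth = fn.SyntheticSpeciesTruth({"env_1": 4.0}, (500, 3500), seed=12)
    occ = fn.generate_species(stack, truth, 200)
    eligible = np.zeros(stack.shape, dtype=bool)
    eligible.ravel()[_eligible_cells(stack, truth)] = True
    background = sample_background(eligible, stack, seed=13)
    presence = extract_env_at_points(stack, occ, stack.layer_names)
    model = fit_maxent(presence, background, fc=("L", "Q"), rm=1.0)
    prediction = predict_over_mask(model, stack, eligible)
    return {
        "stack": stack,
        "truth": truth,
        "occ": occ,
        "eligible": eligible,
        "background": background,
        "presence": presence,
        "model": model,
        "prediction": prediction,
        "true_suitability": true_suitability(stack, truth),
    }


@pytest.fixture(scope="session")
def random_prediction_setup():
    """Uniform random prediction on a 100x100 M with 50 uniform test points."""
    stack = fn.generate_landscape(100, 100, 2, 0.0, None, 99)
    prediction = np.random.default_rng(1).uniform(size=(100, 100))
    idx = np.random.default_rng(2).choice(100 * 100, size=50, replace=False)
    rows, cols = np.unravel_index(idx, (100, 100))
    occ = occurrences_at_cells(stack, zip(rows, cols), species="random")
    return stack, prediction, occ
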