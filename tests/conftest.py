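import numpy as np
import pytest

from gbmspatial.classify import classify_cells
from gbmspatial.sdm import (
    TrainingConfig,
    quadrat_dataset,
    scale_and_split,
    smote_balance,
    train_sdm,
)
from gbmspatial.synthetic import SimulationConfig, simulate_niche_tissue, simulate_sdm_dataset


@pytest.fixture(scope="session")
def sdm_cohort():
    """Synthetic imaging cohort with the default planted texture association."""
    config = SimulationConfig(seed=1)
    cells, quadrats, truth = simulate_sdm_dataset(config, 1)
    classified = classify_cells(cells)
    X, y, meta = quadrat_dataset(
        classified, quadrats, 199.0, fov_size=(config.fov_width, config.fov_height)
    )
    return {
        "config": config,
        "cells": cells,
        "classified": classified,
        "quadrats": quadrats,
        "truth": truth,
        "X": X,
        "y": y,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def trained_model(sdm_cohort):
    """One trained replicate of the funnel network on the planted cohort."""
    rng = np.random.default_rng(5)
    split = scale_and_split(sdm_cohort["X"], sdm_cohort["y"], seed=rng)
    Xs, y = split["X"], split["y"]
    tr, va, te = split["train"], split["val"], split["test"]
    X_tr, y_tr, _ = smote_balance(Xs[tr], y[tr], 5, rng)
    fit = train_sdm(X_tr, y_tr, Xs[va], y[va], config=TrainingConfig(seed=5))
    return {"fit": fit, "model": fit.model, "Xs": Xs, "y": y, "split": split}


@pytest.fixture(scope="session")
def niche_tissue():
    """Default concentric-ring transcriptomics tissue."""
    cells, counts, truth = simulate_niche_tissue(seed=3)
    return {"cells": cells, "counts": counts, "truth": truth}
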