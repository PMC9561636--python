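import numpy as np
import pytest

from phenoscreen.catalogue import get_catalogue
from phenoscreen.synthgen import (
    DEFAULT_PROFILES,
    NoiseModel,
    PlateSpec,
    make_layout,
    sample_plates,
)


@pytest.fixture(scope="session")
def panel_a():
    return get_catalogue("panelA")


@pytest.fixture(scope="session")
def panel_mito():
    return get_catalogue("panelMito")


def two_class_layouts(n_plates=2, panel="panelA", seed=0, spiked=0):
    spec = PlateSpec(panel=panel, seed=seed)
    return [
        make_layout(
            spec,
            [("control", "fill"), ("mutant", "fill")],
            compounds=["PEP005", "prostratin"] if spiked else None,
            n_spiked_per_compound=spiked,
            spike_from="mutant",
            seed=seed + i,
            plate_id=f"P{i + 1}",
        )
        for i in range(n_plates)
    ]


@pytest.fixture(scope="session")
def raw_table(panel_a):
    """Two clean plates, control vs mutant, default noise, no spikes."""
    table, truths = sample_plates(
        two_class_layouts(2, seed=11),
        panel_a,
        DEFAULT_PROFILES,
        NoiseModel(outlier_rate=0.0),
        seed=11,
    )
    return table


@pytest.fixture(scope="session")
def processed_table(raw_table):
    from phenoscreen.prep import preprocess

    table, _ = preprocess(raw_table, "control")
    return table


@pytest.fixture(scope="session")
def svm_model(processed_table):
    from phenoscreen.profclass import CVSpec, train_reference

    return train_reference(
        processed_table, "control", "mutant", "SVM", CVSpec(n_repeats=10, seed=5)
    )


def planted_feature_table(n_per_class=100, n_noise=20, effect=1.4, cv=0.10, seed=0):
    """One informative feature + pure-noise features, two conditions."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    cond = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    sigma = np.sqrt(np.log1p(cv**2))

    def ln(size):
        return rng.lognormal(-sigma**2 / 2, sigma, size)

    data = {"plate_id": "P1", "well": [f"W{i:04d}" for i in range(n)], "condition": cond}
    data["informative"] = ln(n) * np.where(cond == "pos", effect, 1.0)
    for j in range(n_noise):
        data[f"noise_{j:02d}"] = ln(n)
    return pd.DataFrame(data)
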