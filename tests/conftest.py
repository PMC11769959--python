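import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from metabolink import (ConcentrationMatrix, StageSequence, generate_dataset,
                        make_truth, plant_markers, zscore_normalize)

STAGES5 = ("hESC", "EB", "Rosette", "hNPC", "Neuron")


@pytest.fixture
def stages5():
    return StageSequence(STAGES5)


@pytest.fixture
def toy_matrix(stages5):
    """15 samples (5 stages x 3 replicates), 5 metabolites; deterministic."""
    rng = np.random.default_rng(42)
    values = rng.gamma(shape=2.0, scale=1.5, size=(15, 5))
    return ConcentrationMatrix(
        values=values,
        sample_ids=[f"{s}_r{r}" for s in STAGES5 for r in (1, 2, 3)],
        stage_labels=[s for s in STAGES5 for _ in range(3)],
        replicate_ids=[str(r) for _ in STAGES5 for r in (1, 2, 3)],
        metabolite_names=[f"met{j}" for j in range(1, 6)],
    )


@pytest.fixture
def toy_csv(tmp_path, toy_matrix):
    path = tmp_path / "toy.csv"
    toy_matrix.write_csv(path)
    return path


@pytest.fixture
def synth_dataset(stages5):
    """Small synthetic 5-stage dataset with one planted marker set."""
    truth = make_truth(20, StageSequence(STAGES5), density=0.08, seed=7)
    markers = ["M003", "M011", "M017"]
    truth = plant_markers(truth, ("EB", "Rosette"), markers, shift=3.0)
    data = generate_dataset(truth, n_rep=8, seed=70)
    return truth, data


@pytest.fixture
def synth_normalized(synth_dataset):
    _, data = synth_dataset
    return zscore_normalize(data)
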