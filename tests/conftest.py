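import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from maxmarker.core import CellLabelVector, ExpressionMatrix
from maxmarker.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def golden_dataset():
    """Reference synthetic dataset (seed 7) shared by end-to-end tests."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def golden_fixture_dir(golden_dataset, tmp_path_factory):
    """Seed-7 dataset written to disk as an MTX triplet with sidecars."""
    from maxmarker.synthetic import write_fixture

    directory = tmp_path_factory.mktemp("fixture_seed7")
    write_fixture(golden_dataset, directory)
    return directory


@pytest.fixture
def toy_matrix():
    """Tiny matrix: g1 a perfect marker of type A, g2/g3 uninformative."""
    values = np.array(
        [
            # g1   g2   g3
            [5.0, 1.0, 0.0],
            [4.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return ExpressionMatrix(values, tuple(f"c{i}" for i in range(5)), ("g1", "g2", "g3"))


@pytest.fixture
def toy_labels():
    return {"c0": "A", "c1": "A", "c2": "B", "c3": "B", "c4": "B"}


@pytest.fixture
def toy_label_vector(toy_labels):
    return CellLabelVector(toy_labels, "A")
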