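import numpy as np
import pytest

from qsarforest import ActivityLabels, Dataset, DescriptorMatrix


def make_dataset(values, labels=None, ids=None, names=None) -> Dataset:
    """Small labeled dataset from a plain nested list/array."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    ids = ids or [f"chem{i}" for i in range(n)]
    names = names or [f"D{j + 1}" for j in range(d)]
    matrix = DescriptorMatrix(ids, names, values)
    lab = None if labels is None else ActivityLabels(ids, np.asarray(labels))
    return Dataset(matrix, lab)


@pytest.fixture
def separable_dataset() -> Dataset:
    """20 chemicals split perfectly by D1 <= 0.5; D2 is noise."""
    rng = np.random.default_rng(42)
    x1 = np.concatenate([rng.uniform(0, 0.45, 10), rng.uniform(0.55, 1, 10)])
    x2 = rng.uniform(0, 1, 20)
    labels = np.array([0] * 10 + [1] * 10)
    return make_dataset(np.column_stack([x1, x2]), labels)


@pytest.fixture
def xor_dataset() -> Dataset:
    """40 chemicals with XOR structure on two descriptors (no single split
    separates the classes, a depth-2 tree does)."""
    rng = np.random.default_rng(7)
    quads = []
    labels = []
    for qx, qy in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        x = rng.uniform(qx * 0.5 + 0.05, qx * 0.5 + 0.45, 10)
        y = rng.uniform(qy * 0.5 + 0.05, qy * 0.5 + 0.45, 10)
        quads.append(np.column_stack([x, y]))
        labels += [qx ^ qy] * 10
    return make_dataset(np.vstack(quads), np.array(labels))
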