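import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import fatesimplex as fs


@pytest.fixture(scope="session")
def fixture_data():
    """A seeded default synthetic dataset shared across read-only tests."""
    spec = fs.FixtureSpec(seed=11)
    matrix, annotation, graph, truth = fs.generate(spec)
    return spec, matrix, annotation, graph, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_matrix():
    values = np.array([[1.0, 0.0], [2.0, 5.0], [0.0, 3.0]])
    return fs.ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2"])
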