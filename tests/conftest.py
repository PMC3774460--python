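import numpy as np
import pytest

from hospeval.indicator_system import IndicatorHierarchy, load_hierarchy, default_hierarchy
from hospeval.preprocessing import normalize_matrix
from hospeval.synthetic_data import SimConfig, simulate_hospitals


@pytest.fixture(scope="session")
def hierarchy() -> IndicatorHierarchy:
    return default_hierarchy()


@pytest.fixture(scope="session")
def sim_default(hierarchy):
    """Frozen default simulation: 14 hospitals, seed 42."""
    matrix, q = simulate_hospitals(SimConfig(seed=42), hierarchy)
    return matrix, q


@pytest.fixture(scope="session")
def norm_default(hierarchy, sim_default):
    matrix, _ = sim_default
    return normalize_matrix(matrix, hierarchy)


def make_random_hierarchy(rng: np.random.Generator, *, max_children: int = 4):
    """Full-precision random hierarchy (sibling weights sum to exactly 1)."""

    def dirichlet(k):
        w = rng.dirichlet(np.ones(k) * 5)
        w[-1] = 1.0 - w[:-1].sum()  # exact unit sum despite fp
        return w

    n1 = int(rng.integers(2, max_children + 1))
    w1 = dirichlet(n1)
    doc = {"name": "synthetic", "level1": []}
    leaf_counter = 0
    for i in range(n1):
        n2 = int(rng.integers(1, max_children + 1))
        w2 = dirichlet(n2)
        l2s = []
        for j in range(n2):
            n3 = int(rng.integers(1, max_children + 1))
            w3 = dirichlet(n3)
            leaves = []
            for k in range(n3):
                attr = rng.choice(["+", "-", "0"])
                leaves.append(
                    {
                        "id": f"leaf{leaf_counter}",
                        "name": f"leaf {leaf_counter}",
                        "weight": float(w3[k]),
                        "attribute": str(attr),
                        "reference": [40, 60] if attr == "0" else None,
                        "unit": "",
                    }
                )
                leaf_counter += 1
            l2s.append({"name": f"b{i}.{j}", "weight": float(w2[j]), "leaves": leaves})
        doc["level1"].append({"name": f"b{i}", "weight": float(w1[i]), "level2": l2s})
    return load_hierarchy(doc, weight_tol=1e-9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
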