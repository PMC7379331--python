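import numpy as np
import pandas as pd
import pytest

from shapemorph import TriangleMesh, make_template


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    """Cube of side 2 centred at the origin: 8 vertices, 12 outward triangles."""
    v = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 3, 2], [0, 2, 1],  # bottom
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # front
            [3, 7, 6], [3, 6, 2],  # back
            [1, 2, 6], [1, 6, 5],  # right
            [0, 4, 7], [0, 7, 3],  # left
        ]
    )
    return TriangleMesh(v, f).validate()


@pytest.fixture
def sphere_template():
    """Equal-axis (radius 10) template with labeling, level 3."""
    return make_template("test_sphere", subdivision_level=3, axis_lengths=(10.0, 10.0, 10.0))


@pytest.fixture
def small_cohort_table() -> pd.DataFrame:
    """Deterministic 12-subject cohort table with covariates."""
    rng = np.random.default_rng(42)
    n = 12
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": [1] * 6 + [0] * 6,
            "age": rng.normal(23, 4, n),
            "sex": rng.integers(0, 2, n),
            "icv_mm3": rng.normal(1.45e6, 1.5e5, n),
        }
    )
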