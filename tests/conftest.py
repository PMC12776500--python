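import numpy as np
import pytest
from shapely.geometry import Polygon

from misalign import FieldSpec, LmsConfig, generate_field, lms_scores


def ellipse(cx, cy, a, b, angle_deg, n=32):
    """Discretized ellipse polygon with semi-axes a >= b at the given angle."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ca, sa = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return Polygon(np.column_stack([ca * x - sa * y + cx, sa * x + ca * y + cy]))


def axial_diff(a, b):
    """Independent scalar oracle for the axial angular difference."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture(scope="session")
def uniform_field():
    """A dense field with uniformly random axial orientations."""
    return generate_field(
        FieldSpec(n_cells=600, width=700, height=700, noise_model="uniform", seed=11)
    )


@pytest.fixture(scope="session")
def aligned_field():
    """A perfectly aligned field (every orientation at 30°)."""
    return generate_field(
        FieldSpec(n_cells=400, width=600, height=600, mean_orientation_deg=30.0, seed=7)
    )


@pytest.fixture(scope="session")
def uniform_scores(uniform_field):
    cells, _ = uniform_field
    return lms_scores(cells, LmsConfig(radius=60.0))
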