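import numpy as np
import pytest

from invaquant import CellMask, CellSpec, SynthSpec, generate_spheroid_image, random_cells
from invaquant.core import BeadCircle


@pytest.fixture
def centered_spec():
    """512×512 px scene at 1 μm/px with a 50 μm bead at the image center."""
    return SynthSpec(seed=0)


@pytest.fixture
def busy_scene():
    """Rendered scene with 30 random disc cells plus its ground truth."""
    spec = SynthSpec(seed=7)
    spec = SynthSpec(seed=7, cells=random_cells(30, spec))
    return generate_spheroid_image(spec)


def truth_mask(truth) -> CellMask:
    """CellMask built from a scene's ground-truth rendering and true bead."""
    return CellMask(mask=truth.cell_mask, pixel_size=truth.pixel_size, bead=truth.bead)


def random_mask(rng: np.random.Generator, shape=(96, 96), pixel_size=1.0,
                density=0.08) -> CellMask:
    """Random sparse mask with a random in-bounds bead, for property tests."""
    ny, nx = shape
    bead = BeadCircle(
        center_x=float(rng.uniform(0.25, 0.75) * (nx - 1) * pixel_size),
        center_y=float(rng.uniform(0.25, 0.75) * (ny - 1) * pixel_size),
        radius=float(rng.uniform(5.0, 15.0)),
    )
    mask = rng.random(shape) < density
    return CellMask(mask=mask, pixel_size=pixel_size, bead=bead)
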