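import numpy as np
import pytest

from actinquant import synth


@pytest.fixture
def single_fibre_cell():
    """Noiseless image containing one horizontal fibre (50 x 3 px)."""
    spec = synth.CellSpec(
        pattern_shape="none",
        image_size=128,
        fibres=(synth.FibreSpec(centre=(64, 64), length=50, width=3, orientation=0),),
        n_nuclei=0,
    )
    channels, truth = synth.generate_micropattern_cell(spec)
    return channels, truth, spec


def random_fibre_specs(rng, n, image_size=256):
    """Single-fibre specs spanning the morphometric recovery range."""
    out = []
    for _ in range(n):
        out.append(
            synth.FibreSpec(
                centre=(image_size / 2, image_size / 2),
                length=float(rng.uniform(20, 200)),
                width=float(rng.uniform(2, 8)),
                orientation=float(rng.uniform(-90, 90)),
            )
        )
    return out


def angular_diff(a, b):
    """Distance between two axial orientations in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
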