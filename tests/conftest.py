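import numpy as np
import pytest

from spinefret import synthcell
from spinefret.spinemorph import SpineGeometry


@pytest.fixture(scope="session")
def clean_fret_scene():
    """Noise-free, drift-free, bleach-free FRET scene with zero background."""
    spec = synthcell.SceneSpec(
        "fret_timelapse",
        shape=(120, 120),
        n_frames=6,
        background_level=0.0,
        seed=11,
    )
    return spec, *synthcell.make_fret_scene(
        spec, n_rois=4, responder_fraction=0.5, step_amplitude=0.3
    )


@pytest.fixture(scope="session")
def clean_actin_scene():
    spec = synthcell.SceneSpec(
        "actin_dualstain", shape=(160, 160), background_level=0.0, seed=12
    )
    stack, truth = synthcell.make_actin_scene(
        spec, enrichment=0.4, ring_width_um=1.0
    )
    return spec, stack, truth


@pytest.fixture(scope="session")
def dendrite_scene():
    spec = synthcell.SceneSpec(
        "dendrite_spines", shape=(300, 400), background_level=0.0, seed=13
    )
    geometries = [
        SpineGeometry(1.5, 0.2, 0.9),   # mushroom
        SpineGeometry(4.5, 0.3, 0.3),   # filopodium
        SpineGeometry(0.8, 0.5, 0.6),   # stubby
        SpineGeometry(1.5, 0.2, 0.5),   # thin
    ]
    stack, labels, truth = synthcell.make_dendrite_scene(spec, geometries)
    return spec, geometries, stack, labels, truth


def sample_spine_geometries(rng: np.random.Generator, n: int):
    """Random spine geometries over the morphometric sweep ranges.

    Lengths 0.5-6 µm, necks 0.1-0.8 µm, heads 0.2-1.5 µm, with the
    realism constraints head >= neck and length >= head + 0.2 µm (a spine
    whose head spans its whole length has no neck to render).
    """
    out = []
    while len(out) < n:
        length = rng.uniform(0.5, 6.0)
        neck = rng.uniform(0.1, 0.8)
        head = rng.uniform(max(neck, 0.2), 1.5)
        if length < head + 0.2:
            continue
        out.append(SpineGeometry(length, neck, head))
    return out
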