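import numpy as np
import pytest

from restmap.masks import GrayMatterMask, default_tissue_masks, generate_mask
from restmap.synthetic import Community, EffectSpec, octant_partition


@pytest.fixture(scope="session")
def small_mask() -> GrayMatterMask:
    """~500-voxel ellipsoid mask on a 12^3 grid at 3 mm."""
    return generate_mask((12, 12, 12), (15.0, 15.0, 15.0), 3.0)


@pytest.fixture(scope="session")
def box_mask() -> GrayMatterMask:
    """Fully-filled 5x5x4 grid (100 voxels) for exact constructions."""
    return GrayMatterMask(np.ones((5, 5, 4), dtype=bool), voxel_size_mm=3.0)


@pytest.fixture(scope="session")
def mask3() -> GrayMatterMask:
    """Three-voxel mask for hand-checkable degree computations."""
    m = np.zeros((3, 3, 3), dtype=bool)
    m[0, 0, 0] = m[1, 1, 1] = m[2, 2, 2] = True
    return GrayMatterMask(m, voxel_size_mm=3.0)


def hub_effect_spec(mask, coupling=None) -> tuple[EffectSpec, np.ndarray]:
    """Octant-partitioned community structure with one designated hub.

    Returns the spec and the hub's voxel indices.  The hub octant gets
    the given per-subgroup coupling (default: collapsed in male
    patients); all other octants couple at w=1, so degree maps are
    link-driven across the whole mask.
    """
    wm, csf = default_tissue_masks(mask)
    tissue = mask.extract(wm | csf).astype(bool)
    parts = octant_partition(mask, exclude=tissue)
    labels = sorted(k for k in parts if k.startswith("octant"))
    hub_label = labels[-1]
    coupling = coupling or {"FESm": 0.2, "FESf": 1.0, "HCm": 1.0, "HCf": 1.0}
    communities = [
        Community("hub", parts[hub_label], coupling)
        if label == hub_label
        else Community(label, parts[label], 1.0)
        for label in parts
    ]
    return EffectSpec(communities=communities, noise_sd=1.0), parts[hub_label]
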