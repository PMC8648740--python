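"""Shared fixtures: small geometric masks, phantom cases, and a small
synthetic cohort reused across test modules (session-scoped: phantom feature
extraction is the expensive step)."""

import numpy as np
import pytest

from radgen.image import CHANNELS, ImageVolume, StudyCase, TumorMask
from radgen.synthetic import (PhantomSpec, TextureParams, default_phantom_spec,
                              generate_cohort, generate_phantom_case)


def make_sphere_mask(radius: int = 10, spacing=(1.0, 1.0, 1.0)) -> TumorMask:
    n = 2 * radius + 5
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    vox = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius ** 2
    return TumorMask(vox.astype(np.uint8), spacing)


def make_cube_mask(side: int = 17, spacing=(1.0, 1.0, 1.0)) -> TumorMask:
    n = side + 6
    vox = np.zeros((n, n, n), dtype=np.uint8)
    vox[3:3 + side, 3:3 + side, 3:3 + side] = 1
    return TumorMask(vox, spacing)


def make_case(seed: int = 0, group: str = "1", field_strength: str = "1.5T",
              radius: float = 8.0) -> StudyCase:
    spec = default_phantom_spec(group, seed=seed, field_strength=field_strength)
    spec = PhantomSpec(group_label=spec.group_label, base_radius_mm=radius,
                       irregularity=spec.irregularity,
                       texture_params=spec.texture_params,
                       field_strength=field_strength,
                       batch_offset=spec.batch_offset, seed=seed)
    return generate_phantom_case(spec, case_id=f"case_{seed:03d}")


@pytest.fixture(scope="session")
def sphere_mask():
    return make_sphere_mask(10)


@pytest.fixture(scope="session")
def small_case():
    return make_case(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """30-case cohort with default group structure; used by clustering,
    pipeline and perturbation tests."""
    return generate_cohort(n_cases=30, seed=7)
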