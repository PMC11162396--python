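"""Shared fixtures: small, fast phantom geometries for the whole suite."""

import numpy as np
import pytest

from cryodist import (
    DepotSpec,
    ImageStack,
    ImagingConfig,
    TissueSpec,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_tissue() -> TissueSpec:
    """A 3.6 × 3.6 × 2.4 mm block — big enough for µL-scale depots, fast."""
    return TissueSpec(block_extent=(3600.0, 3600.0, 2400.0), embedding_margin=400.0)


@pytest.fixture(scope="session")
def sphere_depot() -> DepotSpec:
    """A ~1 µL spherical depot centred in the small block."""
    return DepotSpec(
        shape_kind="sphere",
        center=(2200.0, 2200.0, 1200.0),
        size_params={"radius": 620.35},
    )


@pytest.fixture(scope="session")
def sphere_phantom(small_tissue, sphere_depot):
    return make_phantom(sphere_depot, small_tissue, grid_spacing=20.0, seed=11)


def noise_free_config(**overrides) -> ImagingConfig:
    """Imaging with PSF, noise and bleed-through all switched off."""
    base = dict(
        psf_sigma_inplane=0.0,
        poisson_gain=0.0,
        gaussian_sd=0.0,
        bleedthrough_attenuation_length=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return ImagingConfig(**base)


def random_stack(
    seed: int, n_sections: int = 6, shape: tuple[int, int] = (40, 48),
    bit_depth: int = 16,
) -> ImageStack:
    """A reproducible random two-channel stack for I/O and crop tests."""
    rng = np.random.default_rng(seed)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    hi = 2**bit_depth - 1
    return ImageStack(
        fluorescence=rng.integers(0, hi, (n_sections, *shape)).astype(dtype),
        reflection=rng.integers(0, hi, (n_sections, *shape)).astype(dtype),
        pixel_pitch=13.66,
        slice_thickness=48.0,
        bit_depth=bit_depth,
        channel_meta={"fluorescence": {"emission_nm": 620.0}},
        provenance="synthetic test stack",
    )
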