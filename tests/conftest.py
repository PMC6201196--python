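"""Shared fixtures: rasterized reference shapes and small phantom fields."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucleomorph import ImageField, NucleusMask, PhantomSpec, generate_field

PX = 0.2  # μm/px, the default phantom scale


def rasterize_disc(radius_px: float, size: int | None = None) -> np.ndarray:
    size = size or int(2 * radius_px + 24)
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def rasterize_ellipse(a_px: float, b_px: float, size: int | None = None) -> np.ndarray:
    """Axis-aligned filled ellipse with semi-axes (a, b) px (a along cols)."""
    size = size or int(2 * max(a_px, b_px) + 24)
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0


def ramanujan_perimeter(a: float, b: float) -> float:
    """Closed-form ellipse perimeter (semi-axes a, b; Ramanujan's approx)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def as_mask(arr: np.ndarray, pixel_size_um: float = PX, **kw) -> NucleusMask:
    return NucleusMask(label_id=1, mask=arr, offset=(0,) * arr.ndim,
                       pixel_size_um=pixel_size_um, **kw)


@pytest.fixture(scope="session")
def disc_mask() -> NucleusMask:
    """Disc of radius 200 px on a 512×512 grid."""
    return as_mask(rasterize_disc(200, 512))


@pytest.fixture(scope="session")
def normal_field():
    """20 normal nuclei, rim ratio 2, noise off."""
    spec = PhantomSpec(n_nuclei=20, field_size=(1024, 1024), seed=7)
    field, truth = generate_field(spec)
    return spec, field, truth


@pytest.fixture(scope="session")
def mixed_field():
    """30 nuclei over all shape classes with mislocalization + myotubes."""
    spec = PhantomSpec(
        n_nuclei=30,
        field_size=(1024, 1024),
        seed=11,
        shape_mix={
            frozenset(): 0.6,
            "elongated": 0.1,
            "blebs": 0.1,
            "strings": 0.08,
            "jellybean": 0.06,
            "severely_deformed": 0.06,
        },
        foci_fraction=0.3,
        honeycomb_fraction=0.3,
        capping_fraction=0.3,
        emerin_foci_fraction=0.3,
        myotube_fraction=0.4,
    )
    field, truth = generate_field(spec)
    return spec, field, truth


@pytest.fixture(scope="session")
def stack_field():
    """Small 3D stack with normal + elongated nuclei and myotubes."""
    spec = PhantomSpec(
        n_nuclei=8,
        field_size=(24, 512, 512),
        z_step_um=0.5,
        seed=2,
        shape_mix={frozenset(): 0.5, "elongated": 0.5},
        foci_fraction=0.5,
        capping_fraction=0.5,
        myotube_fraction=0.5,
    )
    field, truth = generate_field(spec)
    return spec, field, truth


def match_truth(truth_table, row, pixel_size_um: float = PX):
    """Ground-truth row nearest (in centroid) to a measured nucleus row."""
    d = (truth_table.centroid_row - row.centroid_y_um / pixel_size_um) ** 2 + (
        truth_table.centroid_col - row.centroid_x_um / pixel_size_um
    ) ** 2
    return truth_table.loc[d.idxmin()]


def make_field_from_mask(mask: np.ndarray, level: float = 200.0, px: float = PX) -> ImageField:
    return ImageField(channels={"dna": mask.astype(float) * level}, pixel_size_um=px)
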