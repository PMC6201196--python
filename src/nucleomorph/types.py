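"""Core data containers shared across the pipeline.

All physical quantities are expressed in micrometres (μm); image arrays are
indexed ``(row, col)`` for 2D fields and ``(plane, row, col)`` for z-stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Recognised shape-abnormality labels.  An empty label set means the nucleus
#: is normal (circular/oval with no shape defects).
SHAPE_LABELS: tuple[str, ...] = (
    "jellybean",
    "severely_deformed",
    "blebs",
    "strings",
    "elongated",
)

#: Channel roles understood by the pipeline.
CHANNEL_ROLES: tuple[str, ...] = ("dna", "lamin_ac", "lamin_b1", "emerin", "myhc")


class PipelineError(RuntimeError):
    """Base class for typed pipeline errors."""


class MissingMetadataError(PipelineError):
    """Required metadata (pixel size, z-step, channel) is absent."""


class FieldTooCrowdedError(PipelineError):
    """Phantom placement failed after bounded retries."""


@dataclass
class ImageField:
    """One acquired or simulated field of view.

    Parameters
    ----------
    channels : dict
        Maps a channel role (see :data:`CHANNEL_ROLES`) to its intensity
        array.  All arrays share one shape: ``(rows, cols)`` for 2D or
        ``(planes, rows, cols)`` for a z-stack.
    pixel_size_um : float
        Lateral pixel size in μm/px.
    z_step_um : float, optional
        Axial step in μm between planes (3D only).
    field_id : str
        Identifier carried into per-nucleus tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: Optional[float] = None
    field_id: str = "field0"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise MissingMetadataError("pixel_size_um must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def is_3d(self) -> bool:
        return any(c.ndim == 3 for c in self.channels.values())

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise MissingMetadataError(f"channel role {role!r} not present") from None


@dataclass
class NucleusMask:
    """A single segmented nucleus stored as a cropped binary mask + offset.

    ``mask`` is a tight boolean crop; ``offset`` locates its top-left
    (2D: ``(row, col)``) or front-top-left (3D: ``(plane, row, col)``) corner
    in field coordinates, 0-based.
    """

    label_id: int
    mask: np.ndarray
    offset: tuple[int, ...]
    pixel_size_um: float
    z_step_um: Optional[float] = None
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if self.mask.ndim == 3 and self.z_step_um is None:
            raise MissingMetadataError("3D mask requires z_step_um")

    @property
    def is_3d(self) -> bool:
        return self.mask.ndim == 3

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        """2D: pixel count × (pixel size)²; 3D: not defined (use volume)."""
        if self.is_3d:
            raise ValueError("area_um2 is a 2D quantity; use volume_um3")
        return float(self.mask.sum()) * self.pixel_size_um**2

    @property
    def volume_um3(self) -> float:
        if not self.is_3d:
            raise ValueError("volume_um3 is a 3D quantity; use area_um2")
        assert self.z_step_um is not None
        return float(self.mask.sum()) * self.pixel_size_um**2 * self.z_step_um

    @property
    def centroid_um(self) -> tuple[float, ...]:
        idx = np.argwhere(self.mask)
        c = idx.mean(axis=0) + np.asarray(self.offset)
        scale = np.full(self.mask.ndim, self.pixel_size_um)
        if self.is_3d:
            scale[0] = self.z_step_um  # type: ignore[assignment]
        return tuple(float(v) for v in c * scale)

    def coords(self) -> np.ndarray:
        """Pixel coordinates of the mask in field frame, shape (n, ndim)."""
        return np.argwhere(self.mask) + np.asarray(self.offset)

    def to_field(self, shape: tuple[int, ...]) -> np.ndarray:
        """Paint the mask into a full-field boolean array of ``shape``."""
        out = np.zeros(shape, dtype=bool)
        sl = tuple(
            slice(o, o + s) for o, s in zip(self.offset, self.mask.shape)
        )
        out[sl] = self.mask
        return out


def crop_from_field(
    field_mask: np.ndarray,
    label_id: int,
    pixel_size_um: float,
    z_step_um: Optional[float] = None,
) -> NucleusMask:
    """Build a :class:`NucleusMask` from a full-field boolean mask."""
    idx = np.argwhere(field_mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    touches = bool((lo == 0).any() or (hi == np.asarray(field_mask.shape)).any())
    return NucleusMask(
        label_id=label_id,
        mask=field_mask[sl].copy(),
        offset=tuple(int(v) for v in lo),
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        touches_border=touches,
    )
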