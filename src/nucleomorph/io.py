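"""TIFF/OME-TIFF reading and writing with pixel-size metadata.

CSV is the interchange format between stages (one row per nucleus); JSON
holds configs and statistics.  All lengths are serialized in μm, never in
pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .types import CHANNEL_ROLES, ImageField, MissingMetadataError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-wide configuration: channel roles, scales and stage parameters."""

    channel_roles: list[str] = dc_field(
        default_factory=lambda: ["dna", "lamin_ac", "lamin_b1", "emerin"]
    )
    pixel_size_um: Optional[float] = None  # override/force
    z_step_um: Optional[float] = None
    condition: str = "monolayer"  # monolayer | construct3d
    line_id: str = "line0"
    repeat_id: int = 1
    classifier: dict = dc_field(default_factory=dict)
    localization: dict = dc_field(default_factory=dict)
    myotube: dict = dc_field(default_factory=dict)
    segmentation: dict = dc_field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def write_field(path: str | Path, field: ImageField) -> None:
    """Write a field as a multi-channel TIFF with resolution metadata.

    Channels are stacked along the first axis in the order of
    :data:`~nucleomorph.types.CHANNEL_ROLES`; the role list and z-step are
    stored in the JSON image description.
    """
    roles = [r for r in CHANNEL_ROLES if r in field.channels]
    roles += [r for r in field.channels if r not in roles]
    data = np.stack([np.asarray(field.channels[r], dtype=np.float32) for r in roles])
    res = 1.0 / field.pixel_size_um  # pixels per μm
    meta: dict = {"channel_roles": ",".join(roles), "unit": "um"}
    if field.z_step_um is not None:
        meta["spacing"] = field.z_step_um
    tifffile.imwrite(
        str(path),
        data,
        resolution=(res, res),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_field(
    path: str | Path,
    config: Optional[PipelineConfig] = None,
    field_id: Optional[str] = None,
) -> ImageField:
    """Read a TIFF written by :func:`write_field` (or compatible).

    Pixel size comes from the TIFF resolution tags unless the config
    overrides it (config wins, with a warning on conflict).  The mandatory
    DNA channel must be present among the mapped roles.
    """
    path = Path(path)
    if not path.exists():
        raise MissingMetadataError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        px_meta: Optional[float] = None
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num > 0:
                px_meta = den / num
        desc: dict = {}
        tag = page.tags.get("ImageDescription")
        if tag is not None:
            try:
                parsed = json.loads(tag.value)
                if isinstance(parsed, dict):
                    desc = parsed
            except (TypeError, ValueError):
                pass
    roles = None
    if "channel_roles" in desc:
        roles = desc["channel_roles"].split(",")
    elif config is not None:
        roles = config.channel_roles
    if roles is None:
        raise MissingMetadataError(f"{path}: no channel-role map in file or config")

    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(roles):
        raise MissingMetadataError(
            f"{path}: {data.shape[0]} channels but {len(roles)} roles"
        )
    channels = {r: np.asarray(data[i], dtype=np.float64) for i, r in enumerate(roles)}
    if "dna" not in channels:
        raise MissingMetadataError(f"{path}: mandatory DNA channel missing")

    px = px_meta
    if config is not None and config.pixel_size_um is not None:
        if px is not None and abs(px - config.pixel_size_um) > 1e-9:
            logger.warning(
                "%s: config pixel size %.4g overrides metadata %.4g",
                path, config.pixel_size_um, px,
            )
        px = config.pixel_size_um
    if px is None:
        raise MissingMetadataError(f"{path}: pixel size absent and not configured")

    z_step = desc.get("spacing")
    if config is not None and config.z_step_um is not None:
        z_step = config.z_step_um
    return ImageField(
        channels=channels,
        pixel_size_um=float(px),
        z_step_um=float(z_step) if z_step is not None else None,
        field_id=field_id or path.stem,
    )
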