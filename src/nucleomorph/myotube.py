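"""Myotube segmentation and myonucleus assignment.

A nucleus is assigned to a myotube when all three criteria hold:

1. it lies within a marker-positive (MyHC/eMyHC/titin) structure
   (≥ ``min_overlap_frac`` of its area inside one structure);
2. that structure is multinucleated (≥ 2 nuclei meeting criterion 1);
3. the marker immunosignal is excluded from the nucleus (mean marker
   intensity inside < ``exclusion_ratio`` × the mean in the surrounding
   structure shell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters

from .types import ImageField, NucleusMask

logger = logging.getLogger(__name__)


@dataclass
class MyotubeConfig:
    min_overlap_frac: float = 0.8
    exclusion_ratio: float = 0.5
    shell_width_um: float = 2.0
    min_structure_area_um2: float = 100.0
    threshold: Optional[float] = None  # absolute override; None = Otsu


@dataclass
class MyotubeAssignment:
    label_id: int
    in_myotube: bool
    criteria_met: tuple[bool, bool, bool]
    structure_id: Optional[int]


def segment_myotubes(
    marker_channel: np.ndarray,
    pixel_size_um: float,
    config: Optional[MyotubeConfig] = None,
) -> np.ndarray:
    """Threshold + connected components on the marker channel.

    Returns a labeled array (0 = background) of marker-positive structures,
    2D or 3D to match the input.  Small specks below
    ``min_structure_area_um2`` (per-plane scale in 3D) are dropped.
    """
    cfg = config or MyotubeConfig()
    img = np.asarray(marker_channel, dtype=np.float64)
    if img.max() <= 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = cfg.threshold if cfg.threshold is not None else filters.threshold_otsu(img)
    binary = img > thr
    # close over nuclear-exclusion holes inside tubes; edge-replicate padding
    # keeps structures at the field border intact through closing/filling
    pad = 4
    padded = np.pad(binary, pad, mode="edge")
    padded = ndi.binary_closing(padded, iterations=3)
    padded = ndi.binary_fill_holes(padded)
    binary = padded[tuple(slice(pad, -pad) for _ in range(binary.ndim))]
    labels, n = ndi.label(binary)
    if n == 0:
        return labels.astype(np.int32)
    min_px = cfg.min_structure_area_um2 / pixel_size_um**2
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for i in range(1, n + 1):
        m = labels == i
        if m.sum() >= min_px:
            out[m] = next_id
            next_id += 1
    return out


def assign_myonuclei(
    nuclei: Sequence[NucleusMask],
    structures: np.ndarray,
    marker_channel: Optional[np.ndarray] = None,
    config: Optional[MyotubeConfig] = None,
) -> list[MyotubeAssignment]:
    """Apply the three myonucleus criteria to each nucleus.

    ``structures`` is the labeled output of :func:`segment_myotubes` (all
    zeros, e.g. when the marker channel is missing, yields all-false
    assignments).  When ``marker_channel`` is ``None`` criterion 3 is
    assumed satisfied for nuclei meeting criterion 1.
    """
    cfg = config or MyotubeConfig()
    assignments: list[MyotubeAssignment] = []
    if structures.max() == 0:
        return [
            MyotubeAssignment(n.label_id, False, (False, False, False), None)
            for n in nuclei
        ]

    # criterion 1: area overlap with one structure
    candidate: dict[int, int] = {}
    for nuc in nuclei:
        sl = tuple(slice(o, o + s) for o, s in zip(nuc.offset, nuc.mask.shape))
        inside = structures[sl][nuc.mask]
        ids, counts = np.unique(inside[inside > 0], return_counts=True)
        structure_id = None
        if len(ids):
            best = int(ids[np.argmax(counts)])
            if counts.max() / nuc.mask.sum() >= cfg.min_overlap_frac:
                structure_id = best
        if structure_id is not None:
            candidate[nuc.label_id] = structure_id

    # criterion 2: multinucleated structures
    per_structure: dict[int, int] = {}
    for sid in candidate.values():
        per_structure[sid] = per_structure.get(sid, 0) + 1

    shell_iter = max(1, int(round(cfg.shell_width_um / nuclei[0].pixel_size_um))) if nuclei else 1
    for nuc in nuclei:
        sid = candidate.get(nuc.label_id)
        c1 = sid is not None
        c2 = bool(c1 and per_structure.get(sid, 0) >= 2)
        c3 = False
        if c1:
            if marker_channel is None:
                c3 = True
            else:
                full = nuc.to_field(structures.shape)
                shell = ndi.binary_dilation(full, iterations=shell_iter) & ~full
                shell &= structures == sid
                inside_mean = float(marker_channel[full].mean())
                shell_mean = float(marker_channel[shell].mean()) if shell.any() else 0.0
                c3 = shell_mean > 0 and inside_mean < cfg.exclusion_ratio * shell_mean
        ok = c1 and c2 and c3
        assignments.append(
            MyotubeAssignment(nuc.label_id, ok, (c1, c2, c3), sid if c1 else None)
        )
    return assignments


def assign_field(
    field: ImageField,
    nuclei: Sequence[NucleusMask],
    marker_role: str = "myhc",
    config: Optional[MyotubeConfig] = None,
) -> list[MyotubeAssignment]:
    """Segment structures from ``marker_role`` and assign all nuclei.

    A missing marker channel yields all-false assignments with a warning,
    never an error.
    """
    if marker_role not in field.channels:
        logger.warning("marker channel %r missing: all nuclei non-myotube", marker_role)
        return [
            MyotubeAssignment(n.label_id, False, (False, False, False), None)
            for n in nuclei
        ]
    marker = field.channels[marker_role]
    structures = segment_myotubes(marker, field.pixel_size_um, config)
    return assign_myonuclei(nuclei, structures, marker, config)
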