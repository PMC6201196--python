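"""Nucleus segmentation and primitive measurements.

Extracts per-nucleus masks from the DNA channel of 2D fields and 3D stacks
and measures area, sub-pixel perimeter and major-axis length in μm.

Recipe (2D): Gaussian smoothing (σ = 1 px) → Otsu threshold → hole fill →
distance-transform watershed split from h-cut marker cores → minimum-area
filter.  The watershed is conservative: a component is split only where the
distance transform has two cores separated by a saddle deeper than
``split_h_um``, so single elongated or indented nuclei are never fragmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as sk_seg

from .types import ImageField, MissingMetadataError, NucleusMask

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    smooth_sigma_px: float = 1.0
    min_area_um2: float = 20.0
    split_h_um: float = 2.5
    threshold: Optional[float] = None  # absolute override; None = Otsu


def _label_components(binary: np.ndarray, split_h_px: float) -> np.ndarray:
    """Connected components with conservative per-component watershed splits.

    Markers are the cores of the distance transform above
    ``dt.max() − split_h_px`` within each component (an h-cut): a smooth
    ridge inside one elongated (or indented) nucleus yields a single
    connected core, while two touching nuclei pinched by more than
    ``split_h_px`` yield two cores and get separated by watershed.
    """
    structure = ndi.generate_binary_structure(binary.ndim, 1)
    labels, n = ndi.label(binary, structure=structure)
    if n == 0:
        return labels
    out = np.zeros_like(labels)
    next_id = 1
    full_conn = np.ones((3,) * binary.ndim, dtype=int)
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        dt = ndi.distance_transform_edt(np.pad(comp, 1))[
            tuple(slice(1, -1) for _ in range(binary.ndim))
        ]
        thr = float(dt.max()) - split_h_px
        cores = dt > max(thr, 0.0)
        markers, n_mark = ndi.label(cores, structure=full_conn)
        if n_mark > 1:
            ws = sk_seg.watershed(-dt, markers=markers, mask=comp)
            for sub in range(1, n_mark + 1):
                piece = ws == sub
                if piece.any():
                    out[sl][piece] = next_id
                    next_id += 1
        else:
            out[sl][comp] = next_id
            next_id += 1
    return out


def _binarize(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    smoothed = ndi.gaussian_filter(img.astype(np.float64), cfg.smooth_sigma_px)
    if cfg.threshold is not None:
        thr = cfg.threshold
    else:
        if smoothed.max() <= smoothed.min():
            return np.zeros(img.shape, dtype=bool)
        thr = filters.threshold_otsu(smoothed)
    binary = smoothed > thr
    return ndi.binary_fill_holes(binary)


def segment_nuclei_2d(
    field: ImageField,
    dna_channel: str = "dna",
    config: Optional[SegmentationConfig] = None,
) -> list[NucleusMask]:
    """Segment nuclei in a 2D field; one :class:`NucleusMask` per nucleus.

    Masks touching the field border are returned with
    ``touches_border=True`` (callers exclude them from statistics).
    """
    cfg = config or SegmentationConfig()
    if field.pixel_size_um is None or field.pixel_size_um <= 0:
        raise MissingMetadataError("pixel size required for segmentation")
    img = field.channel(dna_channel)
    if img.ndim != 2:
        raise ValueError("segment_nuclei_2d expects a 2D field")
    binary = _binarize(img, cfg)
    if not binary.any():
        return []
    split_h_px = cfg.split_h_um / field.pixel_size_um
    labels = _label_components(binary, split_h_px)
    min_px = cfg.min_area_um2 / field.pixel_size_um**2
    return _extract_masks(labels, min_px, field.pixel_size_um, None)


def segment_nuclei_3d(
    field: ImageField,
    dna_channel: str = "dna",
    config: Optional[SegmentationConfig] = None,
) -> list[NucleusMask]:
    """Segment nuclei in a z-stack via 6-connected 3D components."""
    cfg = config or SegmentationConfig()
    if field.z_step_um is None:
        raise MissingMetadataError("z_step_um required for 3D segmentation")
    img = field.channel(dna_channel)
    if img.ndim != 3:
        raise ValueError("segment_nuclei_3d expects a 3D stack")
    if img.shape[0] < 3:
        raise ValueError("3D segmentation requires >= 3 planes")
    anisotropy = field.z_step_um / field.pixel_size_um
    if anisotropy > 10:
        logger.warning("anisotropy ratio %.1f > 10; 3D measures may be coarse", anisotropy)
    binary = _binarize(img, cfg)
    if not binary.any():
        return []
    split_h_px = cfg.split_h_um / field.pixel_size_um
    labels = _label_components(binary, split_h_px)
    min_vox = cfg.min_area_um2 / field.pixel_size_um**2  # per mid-plane scale
    return _extract_masks(labels, min_vox, field.pixel_size_um, field.z_step_um)


def _extract_masks(
    labels: np.ndarray,
    min_px: float,
    pixel_size_um: float,
    z_step_um: Optional[float],
) -> list[NucleusMask]:
    """Crop labeled components into hole-filled :class:`NucleusMask` objects."""
    out: list[NucleusMask] = []
    next_id = 1
    shape = np.asarray(labels.shape)
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        m = labels[sl] == lab
        if m.sum() < min_px:
            continue
        m = ndi.binary_fill_holes(m)
        lo = np.array([s.start for s in sl])
        hi = np.array([s.stop for s in sl])
        touches = bool((lo == 0).any() or (hi == shape).any())
        out.append(
            NucleusMask(
                label_id=next_id,
                mask=m,
                offset=tuple(int(v) for v in lo),
                pixel_size_um=pixel_size_um,
                z_step_um=z_step_um,
                touches_border=touches,
            )
        )
        next_id += 1
    return out


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


def measure_perimeter(mask: NucleusMask) -> float:
    """Sub-pixel boundary length of a 2D mask, in μm.

    Uses a marching-squares contour at level 0.5 on the Gaussian-smoothed
    (σ = 1.5 px) mask, which removes the staircase bias of pixel-edge counting
    (a raw edge count overestimates a disc's perimeter by ~27%, biasing the
    contour ratio low).  Falls back to the binary contour for masks too thin
    to survive smoothing.
    """
    if mask.is_3d:
        raise ValueError("perimeter is a 2D measurement")
    if mask.n_pixels == 0:
        raise ValueError("empty mask has no perimeter")
    contour = _subpixel_contour(mask.mask)
    length = float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
    return length * mask.pixel_size_um


def _subpixel_contour(mask2d: np.ndarray) -> np.ndarray:
    """Outer boundary polygon at the 0.5 level of the σ=1.5 smoothed mask.

    Falls back to the binary contour for masks too thin to survive
    smoothing.  Returns an (n, 2) array of (row, col) vertices.
    """
    padded = np.pad(mask2d.astype(np.float64), 4)
    smoothed = ndi.gaussian_filter(padded, 1.5)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        contours = measure.find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - single pixel after padding always contours
        raise ValueError("could not trace mask boundary")
    # outer boundary = longest contour (holes were filled upstream)
    lengths = [np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in contours]
    return contours[int(np.argmax(lengths))]


def _extreme_points(coords: np.ndarray) -> np.ndarray:
    """Extremes along the axes and diagonals; exact for collinear masks."""
    picks = []
    for proj in (coords[:, 0], coords[:, 1], coords.sum(1), coords[:, 0] - coords[:, 1]):
        picks.append(coords[int(np.argmin(proj))])
        picks.append(coords[int(np.argmax(proj))])
    return np.unique(np.array(picks), axis=0)


def measure_major_axis(mask: NucleusMask) -> float:
    """Major-axis length in μm.

    2D: maximum Feret diameter of the sub-pixel boundary contour (the same
    σ=1.5 smoothed 0.5-level polygon the perimeter uses, so a rasterized
    L-μm ellipse measures L to within a few hundredths of a μm and the
    strict >25 μm elongation rule stays sharp at the boundary).  3D: extent
    of the voxel cloud along its leading principal axis (max − min
    projection onto the first eigenvector of the coordinate covariance),
    with anisotropic voxel scaling.
    """
    if mask.n_pixels == 0:
        raise ValueError("empty mask has no major axis")
    if not mask.is_3d:
        pts = _subpixel_contour(mask.mask)
        try:
            from scipy.spatial import ConvexHull

            hull_pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear / degenerate contours
            hull_pts = _extreme_points(pts)
        d2 = np.sum(
            (hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1
        )
        return float(np.sqrt(d2.max())) * mask.pixel_size_um
    coords = np.argwhere(mask.mask).astype(np.float64)
    assert mask.z_step_um is not None
    scale = np.array([mask.z_step_um, mask.pixel_size_um, mask.pixel_size_um])
    pts = coords * scale
    pts -= pts.mean(axis=0)
    if len(pts) == 1:
        return float(max(scale))
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]
    proj = pts @ axis
    # + one voxel diagonal to account for voxel extent at both ends
    return float(proj.max() - proj.min()) + float(min(scale))


def measure_nucleus(mask: NucleusMask) -> dict:
    """Area/perimeter/major-axis record for one nucleus (units μm)."""
    rec: dict = {
        "label_id": mask.label_id,
        "touches_border": mask.touches_border,
        "major_axis_um": measure_major_axis(mask),
    }
    if mask.is_3d:
        rec["volume_um3"] = mask.volume_um3
        rec["area_um2"] = np.nan
        rec["perimeter_um"] = np.nan
        cz, cy, cx = mask.centroid_um
        rec.update(centroid_z_um=cz, centroid_y_um=cy, centroid_x_um=cx)
    else:
        rec["area_um2"] = mask.area_um2
        rec["perimeter_um"] = measure_perimeter(mask)
        cy, cx = mask.centroid_um
        rec.update(centroid_y_um=cy, centroid_x_um=cx)
    return rec
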