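"""Nuclear contour ratio and multi-label shape classification.

The contour ratio is ``4π·area / perimeter²`` — 1 for a perfect circle,
lower for deformed outlines.  Shape labels are independent rule operators
over a mask: ``elongated`` (major axis > threshold), ``blebs`` (round
protrusion), ``strings`` (thin protrusion), ``jellybean`` (single dominant
midline bend), ``severely_deformed`` (≥ 2 deep boundary concavities).  A
nucleus may carry several labels; the empty set means normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .segmentation import measure_major_axis, measure_perimeter
from .types import SHAPE_LABELS, NucleusMask

logger = logging.getLogger(__name__)


def contour_ratio(area_um2: float, perimeter_um: float) -> float:
    """``4π·A/P²``; dimensionless, 1 for a perfect circle.

    Pure function of the two measurements; monotone decreasing in the
    perimeter at fixed area.
    """
    if area_um2 <= 0 or perimeter_um <= 0:
        raise ValueError("area and perimeter must be strictly positive")
    return 4.0 * math.pi * area_um2 / perimeter_um**2


@dataclass
class ClassifierConfig:
    """Thresholds for the shape-rule operators (lengths in μm)."""

    elongation_threshold_um: float = 25.0
    #: lower edge of the normal circular/oval contour-ratio band; used for
    #: reporting/QC only, never as a classification rule.
    normal_cr_floor: float = 0.79
    bleb_min_diameter_um: float = 1.5
    string_max_width_um: float = 1.25
    string_min_length_um: float = 3.0
    #: midline deviation from its best-fit line, as a fraction of the minor
    #: semi-axis, above which a single smooth bend reads as a jellybean.
    jellybean_bend_threshold: float = 0.15
    severe_concavity_count: int = 2
    #: structuring-element radius separating the main body from protrusions.
    protrusion_scale_um: float = 1.5
    #: minimum outward reach of a protrusion beyond the main body.
    protrusion_min_height_um: float = 0.8
    min_protrusion_area_um2: float = 0.3
    concavity_min_area_um2: float = 1.0
    concavity_min_depth_um: float = 0.5

    def __post_init__(self) -> None:
        if self.elongation_threshold_um <= 0:
            raise ValueError("elongation_threshold_um must be positive")
        if not 0 < self.normal_cr_floor < 1:
            raise ValueError("normal_cr_floor must lie in (0, 1)")


@dataclass
class ShapeMetrics:
    area_um2: float
    perimeter_um: float
    major_axis_um: float
    contour_ratio: float
    solidity: float
    n_concavities: int
    bend_deviation_frac: float
    protrusion_descriptors: list[tuple[float, float]] = dc_field(default_factory=list)
    #: True when the contour ratio falls inside the normal circular/oval band
    #: (QC annotation; not a classification rule).
    in_normal_cr_band: bool = True


@dataclass(frozen=True)
class ShapeLabelSet:
    labels: frozenset

    def __post_init__(self) -> None:
        unknown = self.labels - set(SHAPE_LABELS)
        if unknown:
            raise ValueError(f"unknown shape labels: {sorted(unknown)}")

    @property
    def is_normal(self) -> bool:
        return len(self.labels) == 0

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(sorted(self.labels))


# ---------------------------------------------------------------------------
# geometric operators
# ---------------------------------------------------------------------------


def _main_body(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological opening that strips protrusions at the given scale."""
    selem = morphology.disk(max(1, int(round(radius_px))))
    body = ndi.binary_opening(mask, structure=selem)
    if not body.any():
        return mask
    # opening can disconnect; keep the largest piece as the body
    lab, n = ndi.label(body)
    if n > 1:
        sizes = ndi.sum_labels(body, lab, index=np.arange(1, n + 1))
        body = lab == 1 + int(np.argmax(sizes))
    return body


def _protrusions(
    mask: np.ndarray, body: np.ndarray, px: float, cfg: ClassifierConfig
) -> list[dict]:
    """Residual components of mask−body, with height/width/length in μm."""
    residual = mask & ~body
    if not residual.any():
        return []
    dist_to_body = ndi.distance_transform_edt(~body)
    dist_in_mask = ndi.distance_transform_edt(mask)
    lab, n = ndi.label(residual, structure=ndi.generate_binary_structure(2, 2))
    out = []
    for i in range(1, n + 1):
        comp = lab == i
        area = comp.sum() * px**2
        if area < cfg.min_protrusion_area_um2:
            continue
        height_px = float(dist_to_body[comp].max())
        height = height_px * px
        if height < cfg.protrusion_min_height_um:
            continue
        # head width: largest inscribed diameter of the mask over the
        # residual, so a bleb whose base survives the opening still reads
        # its full head width while a thin string stays thin.
        width = 2.0 * float(dist_in_mask[comp].max()) * px
        coords = np.argwhere(comp).astype(float)
        if len(coords) > 1:
            c = coords - coords.mean(axis=0)
            cov = np.cov(c.T)
            ev = np.linalg.eigvalsh(cov)
            length = 2.0 * 2.0 * math.sqrt(max(ev[-1], 0.0)) * px  # ~4σ extent
        else:
            length = px
        out.append({"area": area, "height": height, "width": width, "length": length})
    return out


def _concavities(body: np.ndarray, px: float, cfg: ClassifierConfig) -> int:
    """Count deep concave regions: hull minus body, filtered by area/depth."""
    hull = morphology.convex_hull_image(body)
    diff = hull & ~body
    if not diff.any():
        return 0
    dist_to_body = ndi.distance_transform_edt(~body)
    lab, n = ndi.label(diff, structure=ndi.generate_binary_structure(2, 2))
    count = 0
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() * px**2 < cfg.concavity_min_area_um2:
            continue
        if float(dist_to_body[comp].max()) * px < cfg.concavity_min_depth_um:
            continue
        count += 1
    return count


def _bend_deviation(body: np.ndarray) -> float:
    """Max deviation of the body midline from its best-fit line, ÷ minor semi-axis.

    The body is rotated into its principal frame; the midline is the mean
    transverse position per longitudinal bin; deviation is measured after
    removing the best-fit line, so straight ellipses score ~0 and smoothly
    bent ones score high.
    """
    coords = np.argwhere(body).astype(float)
    if len(coords) < 20:
        return 0.0
    c = coords - coords.mean(axis=0)
    cov = np.cov(c.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    u = c @ eigvecs[:, -1]  # longitudinal
    v = c @ eigvecs[:, 0]  # transverse
    b = 2.0 * math.sqrt(max(eigvals[0], 1e-9))  # ~minor semi-axis in px
    n_bins = 24
    edges = np.linspace(u.min(), u.max(), n_bins + 1)
    which = np.clip(np.digitize(u, edges) - 1, 0, n_bins - 1)
    mids, centers = [], []
    # trim the extreme 10% at each end where the section is a sliver
    span = u.max() - u.min()
    for k in range(n_bins):
        sel = which == k
        if sel.sum() < 3:
            continue
        cu = 0.5 * (edges[k] + edges[k + 1])
        if cu - u.min() < 0.1 * span or u.max() - cu < 0.1 * span:
            continue
        mids.append(v[sel].mean())
        centers.append(cu)
    if len(mids) < 5:
        return 0.0
    mids_a = np.array(mids)
    centers_a = np.array(centers)
    coef = np.polyfit(centers_a, mids_a, 1)
    resid = mids_a - np.polyval(coef, centers_a)
    return float(np.abs(resid).max() / b)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def compute_shape_metrics(
    mask: NucleusMask, cfg: Optional[ClassifierConfig] = None
) -> ShapeMetrics:
    """All shape descriptors for one 2D nucleus mask."""
    cfg = cfg or ClassifierConfig()
    if mask.is_3d:
        raise ValueError("compute_shape_metrics expects a 2D mask")
    px = mask.pixel_size_um
    area = mask.area_um2
    perim = measure_perimeter(mask)
    cr = contour_ratio(area, perim)
    major = measure_major_axis(mask)
    m = np.pad(mask.mask, 2)
    hull = morphology.convex_hull_image(m)
    solidity = float(m.sum() / hull.sum())
    body = _main_body(m, cfg.protrusion_scale_um / px)
    protr = _protrusions(m, body, px, cfg)
    return ShapeMetrics(
        area_um2=area,
        perimeter_um=perim,
        major_axis_um=major,
        contour_ratio=cr,
        solidity=solidity,
        n_concavities=_concavities(body, px, cfg),
        bend_deviation_frac=_bend_deviation(body),
        protrusion_descriptors=[(p["length"], p["width"]) for p in protr],
        in_normal_cr_band=cr >= cfg.normal_cr_floor,
    )


def classify_shape(
    mask: NucleusMask,
    metrics: Optional[ShapeMetrics] = None,
    cfg: Optional[ClassifierConfig] = None,
) -> ShapeLabelSet:
    """Assign the multi-label shape classification to one nucleus.

    Labels are independent; the empty set means a normal (circular/oval)
    nucleus.  ``elongated`` is exact: major axis strictly greater than
    ``cfg.elongation_threshold_um``.
    """
    cfg = cfg or ClassifierConfig()
    if mask.n_pixels < 4:
        logger.warning(
            "nucleus %d: degenerate %d-pixel mask, falling back to "
            "severely_deformed", mask.label_id, mask.n_pixels,
        )
        return ShapeLabelSet(frozenset({"severely_deformed"}))
    if metrics is None:
        try:
            metrics = compute_shape_metrics(mask, cfg)
        except (ValueError, IndexError):
            logger.warning(
                "nucleus %d: degenerate mask, falling back to severely_deformed",
                mask.label_id,
            )
            return ShapeLabelSet(frozenset({"severely_deformed"}))
    labels = set()
    if metrics.major_axis_um > cfg.elongation_threshold_um:
        labels.add("elongated")
    for length, width in metrics.protrusion_descriptors:
        if width <= cfg.string_max_width_um and length >= cfg.string_min_length_um:
            labels.add("strings")
        elif width >= cfg.bleb_min_diameter_um:
            labels.add("blebs")
    if metrics.n_concavities >= cfg.severe_concavity_count:
        labels.add("severely_deformed")
    if (
        metrics.bend_deviation_frac > cfg.jellybean_bend_threshold
        and metrics.n_concavities <= 1
    ):
        labels.add("jellybean")
    return ShapeLabelSet(frozenset(labels))


def pool_deformed(label_set: ShapeLabelSet) -> bool:
    """Reporting-time pooling of jellybean + severely_deformed into 'deformed'."""
    return "jellybean" in label_set or "severely_deformed" in label_set
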