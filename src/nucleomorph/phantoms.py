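"""Synthetic fluorescence-microscopy phantoms with known ground truth.

Generates 2D fields and 3D z-stacks of nucleus phantoms spanning the shape
taxonomy (normal ellipse, jellybean, severely deformed, blebs, strings,
elongated), a lamina-intensity model (peripheral rim, nucleoplasmic level,
bright foci, interior honeycomb holes, angular capping sectors), optional
multinucleated marker-positive tube regions, and Poisson+Gaussian noise.

Randomness contract
-------------------
All draws derive from ``spec.seed`` through fixed named sub-streams so that a
given ``(spec, seed)`` pair is bit-reproducible and per-nucleus geometry is
stable under re-ordering:

* label draw:   ``np.random.default_rng([seed, STREAM_LABELS])`` — a single
  ``choice`` over the canonically-sorted shape mix.
* flag draws:   ``np.random.default_rng([seed, STREAM_FLAGS])``.
* placement:    ``np.random.default_rng([seed, STREAM_PLACE])``.
* nucleus *i* geometry: ``np.random.default_rng([seed, STREAM_NUCLEUS, i])``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import (
    SHAPE_LABELS,
    FieldTooCrowdedError,
    ImageField,
)

STREAM_LABELS = 0x1ABE1
STREAM_FLAGS = 0xF1A6
STREAM_PLACE = 0x97ACE
STREAM_NUCLEUS = 0x9C


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


def canonical_mix(shape_mix: Mapping) -> list[tuple[frozenset, float]]:
    """Return the shape mix as a list sorted canonically (by label tuple).

    Keys may be frozensets, iterables of labels, or single label strings;
    the empty set denotes a normal nucleus.
    """
    out = []
    for key, p in shape_mix.items():
        if isinstance(key, str):
            labels = frozenset([key]) if key else frozenset()
        else:
            labels = frozenset(key)
        unknown = labels - set(SHAPE_LABELS)
        if unknown:
            raise ValueError(f"unknown shape labels: {sorted(unknown)}")
        out.append((labels, float(p)))
    out.sort(key=lambda kv: tuple(sorted(kv[0])))
    return out


@dataclass
class PhantomSpec:
    """Parameters of one synthetic field.

    ``field_size`` is ``(rows, cols)`` for a 2D field or
    ``(planes, rows, cols)`` for a z-stack (``z_step_um`` then required).
    ``shape_mix`` maps label sets (frozenset of labels, or a single label
    string, or ``frozenset()`` for normal) to probabilities summing to 1.
    """

    n_nuclei: int = 20
    field_size: tuple[int, ...] = (512, 512)
    pixel_size_um: float = 0.2
    z_step_um: Optional[float] = None
    shape_mix: Mapping = dc_field(default_factory=lambda: {frozenset(): 1.0})
    base_axes_um: tuple[float, float] = (15.0, 10.0)
    elongated_length_um: float = 30.0
    rim_ratio: float = 2.0
    rim_width_um: float = 1.0
    n_foci: int = 3
    foci_fraction: float = 0.0
    honeycomb_fraction: float = 0.0
    n_honeycomb_holes: int = 3
    capping_fraction: float = 0.0
    capping_arc_deg: float = 60.0
    emerin_foci_fraction: float = 0.0
    myotube_fraction: float = 0.0
    noise_gaussian_sd: float = 0.0
    noise_poisson_gain: float = 0.0
    seed: int = 0

    # intensity model levels (arbitrary units)
    nucleoplasm_level: float = 100.0
    dna_level: float = 200.0
    myhc_level: float = 150.0
    myhc_nuclear_exclusion: float = 0.15
    focus_contrast: float = 2.5
    hole_level_frac: float = 0.05

    def __post_init__(self) -> None:
        mix = canonical_mix(self.shape_mix)
        total = sum(p for _, p in mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shape_mix probabilities sum to {total}, not 1")
        if any(p < 0 for _, p in mix):
            raise ValueError("shape_mix probabilities must be non-negative")
        if self.rim_ratio < 0:
            raise ValueError("rim_ratio must be >= 0")
        if any("elongated" in labels for labels, p in mix if p > 0):
            if self.elongated_length_um <= 25.0:
                raise ValueError(
                    "elongated_length_um must exceed 25 when the elongated "
                    "label is in the mix"
                )
        if self.base_axes_um[0] > 25.0:
            raise ValueError("base major axis of normal nuclei must be <= 25 um")
        if self.base_axes_um[0] < self.base_axes_um[1]:
            raise ValueError("base_axes_um must be (major, minor)")
        if len(self.field_size) == 3 and self.z_step_um is None:
            raise ValueError("3D field_size requires z_step_um")

    @property
    def is_3d(self) -> bool:
        return len(self.field_size) == 3

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["shape_mix"] = {
            "+".join(sorted(k)) if k else "normal": p
            for k, p in canonical_mix(self.shape_mix)
        }
        d["field_size"] = list(self.field_size)
        d["base_axes_um"] = list(self.base_axes_um)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        mix = {}
        for k, p in d.pop("shape_mix").items():
            labels = frozenset() if k == "normal" else frozenset(k.split("+"))
            mix[labels] = p
        d["shape_mix"] = mix
        d["field_size"] = tuple(d["field_size"])
        d["base_axes_um"] = tuple(d["base_axes_um"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-nucleus truth for one generated field.

    ``table`` has one row per nucleus (``nucleus_id`` matches the positive
    integers in ``label_image``) with true shape labels, major-axis length,
    rim ratio, mislocalization flags, myotube membership and centroid.
    """

    table: pd.DataFrame
    label_image: np.ndarray
    tube_label_image: Optional[np.ndarray] = None

    def mask_of(self, nucleus_id: int) -> np.ndarray:
        return self.label_image == nucleus_id


# ---------------------------------------------------------------------------
# Shape masks
# ---------------------------------------------------------------------------

# geometry constants (fractions of the minor semi-axis b unless noted)
_BEND_FRAC = 0.9          # jellybean midline deviation, × b
_BITE_FRAC = 0.5          # severe-concavity bite radius, × b
_BITE_ANGLES = (70.0, 250.0)
_BLEB_DIAM_FRAC = 0.28    # bleb head diameter, × minor axis (within 10-30%)
_BLEB_ANGLE = 40.0
_STRING_WIDTH_UM = 0.6
_STRING_LENGTH_UM = 4.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = ndi.generate_binary_structure(mask.ndim, 1)  # 4-/6-connected
    lab, n = ndi.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def generate_shape_mask(
    label_set: Sequence[str] | frozenset,
    axes_um: tuple[float, float],
    pixel_size_um: float,
    elongated_length_um: float = 30.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Rasterize one nucleus phantom mask for the requested label set.

    The empty set yields a plain ellipse; ``jellybean`` bends it along an
    arc; ``severely_deformed`` carves two deep boundary bites; ``blebs``
    attaches a circular head (diameter 10-30% of the minor axis);
    ``strings`` attaches a thin protrusion (width ≤ 1 μm, length ≥ 3 μm);
    ``elongated`` stretches the major axis to ``elongated_length_um``
    (> 25 μm).  Labels compose.  The result is 4-connected and hole-free,
    major axis along columns.
    """
    labels = frozenset(label_set)
    unknown = labels - set(SHAPE_LABELS)
    if unknown:
        raise ValueError(f"unknown shape labels: {sorted(unknown)}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    major, minor = axes_um
    if major <= 0 or minor <= 0:
        raise ValueError("axes must be positive")
    if "elongated" in labels:
        major = elongated_length_um

    a = major / 2.0 / pixel_size_um  # semi-axes in px
    b = minor / 2.0 / pixel_size_um
    bend = _BEND_FRAC * b if "jellybean" in labels else 0.0

    string_len = _STRING_LENGTH_UM / pixel_size_um if "strings" in labels else 0.0
    bleb_r = (
        _BLEB_DIAM_FRAC * minor / 2.0 / pixel_size_um if "blebs" in labels else 0.0
    )
    pad = int(math.ceil(max(4, 2 * bleb_r + 4, 4)))
    w = int(math.ceil(2 * a + 2 * string_len + 2 * pad))
    h = int(math.ceil(2 * b + bend + 2 * pad + 2 * bleb_r))
    cy, cx = h / 2.0 + bend / 2.0, w / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - cx
    y = rows - cy

    # base (possibly bent) ellipse: the midline follows  y = -bend * (x/a)^2
    ymid = -bend * (x / a) ** 2
    mask = (x / a) ** 2 + ((y - ymid) / b) ** 2 <= 1.0

    def boundary_point(t_deg: float) -> tuple[float, float]:
        t = math.radians(t_deg)
        bx = a * math.cos(t)
        by = b * math.sin(t) - bend * math.cos(t) ** 2
        return bx, by

    if "severely_deformed" in labels:
        r_bite = _BITE_FRAC * b
        for ang in _BITE_ANGLES:
            bx, by = boundary_point(ang)
            mask &= (x - bx) ** 2 + (y - by) ** 2 > r_bite**2

    if "blebs" in labels:
        t = math.radians(_BLEB_ANGLE)
        bx, by = boundary_point(_BLEB_ANGLE)
        # outward normal of the un-bent ellipse, adequate for small bends
        nx, ny = math.cos(t) / a, math.sin(t) / b
        nn = math.hypot(nx, ny)
        nx, ny = nx / nn, ny / nn
        cx_b = bx + 0.6 * bleb_r * nx
        cy_b = by + 0.6 * bleb_r * ny
        mask |= (x - cx_b) ** 2 + (y - cy_b) ** 2 <= bleb_r**2

    if "strings" in labels:
        w_half = _STRING_WIDTH_UM / 2.0 / pixel_size_um
        bx, by = boundary_point(0.0)
        mask |= (
            (x >= bx - 2)
            & (x <= bx + string_len)
            & (np.abs(y - by) <= w_half)
        )

    mask = ndi.binary_fill_holes(mask)
    mask = _largest_component(mask)
    # tight crop
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return mask[lo[0] : hi[0], lo[1] : hi[1]]


def _rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg % 360.0 == 0.0:
        return mask
    rot = ndi.rotate(mask.astype(np.float32), angle_deg, order=1, reshape=True)
    out = rot > 0.5
    out = ndi.binary_fill_holes(out)
    out = _largest_component(out)
    idx = np.argwhere(out)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return out[lo[0] : hi[0], lo[1] : hi[1]]


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------


def _sample_labels(spec: PhantomSpec) -> list[frozenset]:
    mix = canonical_mix(spec.shape_mix)
    probs = np.array([p for _, p in mix])
    rng = np.random.default_rng([spec.seed, STREAM_LABELS])
    draws = rng.choice(len(mix), size=spec.n_nuclei, p=probs)
    return [mix[i][0] for i in draws]


def _paint_disc(img: np.ndarray, cy: float, cx: float, r: float, value: float) -> None:
    y0, y1 = max(0, int(cy - r - 1)), min(img.shape[0], int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(img.shape[1], int(cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    img[y0:y1, x0:x1][sel] = value


def _nucleus_features(
    footprint: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> dict:
    """Draw per-nucleus feature geometry once (shared across z planes).

    Hole and focus centres are chosen on the full (mid-plane) footprint;
    3D rendering repaints the same positions on every plane they cover, so
    a maximum projection sees coherent features.
    """
    px = spec.pixel_size_um
    dt = ndi.distance_transform_edt(footprint)
    rim_px = spec.rim_width_um / px
    hole_r = 0.8 / px
    interior = footprint & (dt > rim_px + hole_r + 2)
    cand = np.argwhere(interior)
    holes: list[np.ndarray] = []
    if len(cand):
        order = rng.permutation(len(cand))
        for j in order:  # greedy spacing so holes stay distinct patches
            p = cand[j]
            if all(np.hypot(*(p - q)) >= 3.0 * hole_r for q in holes):
                holes.append(p)
            if len(holes) >= spec.n_honeycomb_holes:
                break
    ring = footprint & (dt <= rim_px)
    cand = np.argwhere(ring)
    foci: list[np.ndarray] = []
    if len(cand):
        idx = rng.choice(len(cand), size=min(spec.n_foci, len(cand)), replace=False)
        foci = [cand[i] for i in idx]
    return {
        "hole_centers": holes,
        "hole_r_px": hole_r,
        "foci_centers": foci,
        "focus_r_px": 0.6 / px,
        "cap_start_deg": float(rng.uniform(0, 360)),
        "centroid": np.argwhere(footprint).mean(axis=0),
    }


def _lamin_plane(
    crop_mask: np.ndarray,
    spec: PhantomSpec,
    rim_level: float,
    features: dict,
    honeycomb: bool,
    foci: bool,
    capping: bool,
) -> np.ndarray:
    """Intensity model on one 2D mask crop: rim + nucleoplasm + features."""
    px = spec.pixel_size_um
    dt = ndi.distance_transform_edt(crop_mask)
    rim_px = spec.rim_width_um / px
    out = np.zeros(crop_mask.shape, dtype=np.float64)
    out[crop_mask] = spec.nucleoplasm_level
    out[crop_mask & (dt <= rim_px)] = rim_level

    if honeycomb:
        for cyx in features["hole_centers"]:
            _paint_disc(
                out, cyx[0], cyx[1], features["hole_r_px"],
                spec.hole_level_frac * spec.nucleoplasm_level,
            )
        out[~crop_mask] = 0.0
    if foci:
        focus_r = features["focus_r_px"]
        level = spec.focus_contrast * max(rim_level, spec.nucleoplasm_level)
        for cyx in features["foci_centers"]:
            yy, xx = int(cyx[0]), int(cyx[1])
            y0, y1 = max(0, int(yy - focus_r - 1)), min(out.shape[0], int(yy + focus_r + 2))
            x0, x1 = max(0, int(xx - focus_r - 1)), min(out.shape[1], int(xx + focus_r + 2))
            gy, gx = np.mgrid[y0:y1, x0:x1]
            sel = ((gy - yy) ** 2 + (gx - xx) ** 2 <= focus_r**2) & crop_mask[y0:y1, x0:x1]
            out[y0:y1, x0:x1][sel] = level
    if capping and spec.capping_arc_deg > 0:
        cy, cx = features["centroid"]
        yy, xx = np.mgrid[0 : crop_mask.shape[0], 0 : crop_mask.shape[1]]
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        half = spec.capping_arc_deg / 2.0
        diff = (theta - features["cap_start_deg"] + 180.0) % 360.0 - 180.0
        sector = np.abs(diff) <= half
        out[crop_mask & sector] = 0.0
    return out


def _apply_noise(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float64)
    if spec.noise_poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.noise_poisson_gain) / spec.noise_poisson_gain
    if spec.noise_gaussian_sd > 0:
        dyn = max(float(img.max()), 1.0)
        out = out + rng.normal(0.0, spec.noise_gaussian_sd * dyn, size=img.shape)
    return np.clip(out, 0, None)


def _make_tube_bands(
    spec: PhantomSpec,
    shape_2d: tuple[int, int],
    n_tubes: int,
    band_h_px: Optional[int] = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Horizontal marker-positive bands; returns label image + row ranges."""
    band_h = band_h_px or int(2.4 * spec.base_axes_um[1] / spec.pixel_size_um)
    tube_labels = np.zeros(shape_2d, dtype=np.int32)
    rows = shape_2d[0]
    ranges: list[tuple[int, int]] = []
    gap = max(1, (rows - n_tubes * band_h) // (n_tubes + 1))
    r = gap
    for t in range(n_tubes):
        r0, r1 = r, min(r + band_h, rows)
        tube_labels[r0:r1, :] = t + 1
        ranges.append((r0, r1))
        r = r1 + gap
    return tube_labels, ranges


def generate_field(spec: PhantomSpec) -> tuple[ImageField, GroundTruth]:
    """Generate one synthetic field and its aligned ground truth.

    Returns a DNA channel (filled nuclei), a Lamin A/C channel realizing the
    requested rim ratio plus foci/honeycomb features, a Lamin B1 channel with
    optional capping sectors, an Emerin channel with optional foci, and — when
    ``myotube_fraction > 0`` — a myosin marker channel with multinucleated
    tube bands and nuclear signal exclusion.  Deterministic for a fixed seed.

    Raises
    ------
    FieldTooCrowdedError
        If a nucleus cannot be placed without overlap after bounded retries.
    """
    if spec.is_3d:
        return _generate_field_3d(spec)
    return _generate_field_2d(spec)


def _placement_for(
    spec: PhantomSpec,
    crops: list[np.ndarray],
    in_tube: np.ndarray,
    tube_ranges: list[tuple[int, int]],
    shape_2d: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 300,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Place crops without overlap (2 px clearance, no border contact)."""
    occupancy = np.zeros(shape_2d, dtype=bool)
    offsets: list[tuple[int, int]] = []
    tube_ids: list[int] = []
    band_margin = int(spec.base_axes_um[1] / spec.pixel_size_um)  # keep clear of band edges
    tube_cursor = 0
    for i, crop in enumerate(crops):
        ch, cw = crop.shape
        if ch + 2 >= shape_2d[0] or cw + 2 >= shape_2d[1]:
            raise FieldTooCrowdedError(
                f"nucleus {i} ({ch}x{cw} px) does not fit in field {shape_2d}"
            )
        grown = ndi.binary_dilation(crop, iterations=3)
        placed = False
        fits_band = False
        if in_tube[i] and tube_ranges:
            t = tube_cursor % len(tube_ranges)
            r0, r1 = tube_ranges[t]
            lo = max(1, r0)
            hi = min(shape_2d[0] - ch - 1, r1 - ch)
            fits_band = hi > lo
        for _ in range(max_tries):
            if fits_band:
                row = int(rng.integers(lo, hi + 1))
            else:
                row = int(rng.integers(1, shape_2d[0] - ch - 1))
                if tube_ranges and not in_tube[i]:
                    # keep non-tube nuclei away from the bands
                    mid = row + ch // 2
                    bad = any(
                        r0 - band_margin < mid < r1 + band_margin
                        for r0, r1 in tube_ranges
                    )
                    if bad:
                        continue
            col = int(rng.integers(1, shape_2d[1] - cw - 1))
            sl = (slice(row, row + ch), slice(col, col + cw))
            if not (occupancy[sl] & grown).any():
                occupancy[sl] |= crop
                offsets.append((row, col))
                if fits_band:
                    tube_ids.append((tube_cursor % len(tube_ranges)) + 1)
                    tube_cursor += 1
                else:
                    tube_ids.append(0)
                placed = True
                break
        if not placed:
            raise FieldTooCrowdedError(
                f"could not place nucleus {i} after {max_tries} tries: field too crowded"
            )
    return offsets, tube_ids


def _sample_truth(spec: PhantomSpec) -> tuple[list[frozenset], pd.DataFrame]:
    labels = _sample_labels(spec)
    frng = np.random.default_rng([spec.seed, STREAM_FLAGS])
    n = spec.n_nuclei
    honeycomb = frng.random(n) < spec.honeycomb_fraction
    foci = frng.random(n) < spec.foci_fraction
    capping = frng.random(n) < spec.capping_fraction
    emerin = frng.random(n) < spec.emerin_foci_fraction
    n_myo = int(round(spec.myotube_fraction * n))
    in_tube = np.zeros(n, dtype=bool)
    in_tube[:n_myo] = True  # first nuclei go to tubes; placement assigns bands
    rows = []
    for i, ls in enumerate(labels):
        major = spec.elongated_length_um if "elongated" in ls else spec.base_axes_um[0]
        rows.append(
            {
                "nucleus_id": i + 1,
                "labels": "+".join(sorted(ls)),
                **{f"label_{name}": (name in ls) for name in SHAPE_LABELS},
                "is_normal": len(ls) == 0,
                "major_axis_um": major,
                "rim_ratio": spec.rim_ratio,
                "has_honeycomb": bool(honeycomb[i]),
                "has_foci": bool(foci[i]),
                "has_capping": bool(capping[i]),
                "has_emerin_foci": bool(emerin[i]),
                "in_myotube": bool(in_tube[i]),
            }
        )
    return labels, pd.DataFrame(rows)


def _generate_field_2d(spec: PhantomSpec) -> tuple[ImageField, GroundTruth]:
    labels, truth = _sample_truth(spec)
    n = spec.n_nuclei
    shape_2d = tuple(spec.field_size)  # type: ignore[assignment]

    crops = []
    angles = []
    for i, ls in enumerate(labels):
        nrng = np.random.default_rng([spec.seed, STREAM_NUCLEUS, i])
        base = generate_shape_mask(
            ls, spec.base_axes_um, spec.pixel_size_um, spec.elongated_length_um
        )
        angle = float(nrng.uniform(0, 180))
        crops.append(_rotate_mask(base, angle))
        angles.append(angle)

    in_tube = truth["in_myotube"].to_numpy()
    n_myo = int(in_tube.sum())
    tube_ranges: list[tuple[int, int]] = []
    tube_label_image = None
    if n_myo > 0:
        n_tubes = max(1, n_myo // 4)
        # every tube must be multinucleated
        while n_tubes > 1 and n_myo / n_tubes < 2:
            n_tubes -= 1
        # bands must be tall enough for the largest tube-nucleus crop
        tube_crop_h = max(
            (crops[i].shape[0] for i in range(n) if in_tube[i]), default=0
        )
        band_h_px = max(
            int(2.4 * spec.base_axes_um[1] / spec.pixel_size_um), tube_crop_h + 6
        )
        while n_tubes > 1 and n_tubes * band_h_px > 0.7 * shape_2d[0]:
            n_tubes -= 1
        tube_label_image, tube_ranges = _make_tube_bands(
            spec, shape_2d, n_tubes, band_h_px
        )

    prng = np.random.default_rng([spec.seed, STREAM_PLACE])
    offsets, tube_ids = _placement_for(spec, crops, in_tube, tube_ranges, shape_2d, prng)
    truth["tube_id"] = tube_ids
    counts = pd.Series(tube_ids).value_counts()
    truth["in_myotube"] = [t > 0 and counts[t] >= 2 for t in tube_ids]

    label_image = np.zeros(shape_2d, dtype=np.int32)
    dna = np.zeros(shape_2d)
    lamin_ac = np.zeros(shape_2d)
    lamin_b1 = np.zeros(shape_2d)
    emerin = np.zeros(shape_2d)

    rim_ac = spec.rim_ratio * spec.nucleoplasm_level
    centroids = []
    for i, (crop, (row, col)) in enumerate(zip(crops, offsets)):
        sl = (slice(row, row + crop.shape[0]), slice(col, col + crop.shape[1]))
        label_image[sl][crop] = i + 1
        dna[sl][crop] = spec.dna_level
        nrng = np.random.default_rng([spec.seed, STREAM_NUCLEUS, i, 1])
        feats = _nucleus_features(crop, spec, nrng)
        r = truth.iloc[i]
        lamin_ac[sl] += _lamin_plane(
            crop, spec, rim_ac, feats,
            honeycomb=bool(r["has_honeycomb"]), foci=bool(r["has_foci"]),
            capping=False,
        )
        lamin_b1[sl] += _lamin_plane(
            crop, spec, 1.3 * spec.nucleoplasm_level, feats,
            honeycomb=False, foci=False,
            capping=bool(r["has_capping"]),
        )
        emerin[sl] += _lamin_plane(
            crop, spec, 1.4 * spec.nucleoplasm_level, feats,
            honeycomb=False, foci=bool(r["has_emerin_foci"]),
            capping=False,
        )
        cyx = np.argwhere(crop).mean(axis=0) + np.array([row, col])
        centroids.append(cyx)

    truth["centroid_row"] = [c[0] for c in centroids]
    truth["centroid_col"] = [c[1] for c in centroids]

    channels = {"dna": dna, "lamin_ac": lamin_ac, "lamin_b1": lamin_b1, "emerin": emerin}
    if tube_label_image is not None:
        myhc = np.where(tube_label_image > 0, spec.myhc_level, 0.0)
        # nuclear exclusion of the marker signal
        myhc[label_image > 0] *= spec.myhc_nuclear_exclusion
        channels["myhc"] = myhc

    xrng = np.random.default_rng([spec.seed, 0x0153])
    for role in channels:
        channels[role] = _apply_noise(channels[role], spec, xrng)

    field = ImageField(channels=channels, pixel_size_um=spec.pixel_size_um)
    return field, GroundTruth(truth, label_image, tube_label_image)


def _generate_field_3d(spec: PhantomSpec) -> tuple[ImageField, GroundTruth]:
    """3D stacks: 2D footprints extruded with an elliptic z-profile."""
    labels, truth = _sample_truth(spec)
    nz, ny, nx = spec.field_size
    assert spec.z_step_um is not None
    shape_2d = (ny, nx)

    crops = []
    for i, ls in enumerate(labels):
        nrng = np.random.default_rng([spec.seed, STREAM_NUCLEUS, i])
        base = generate_shape_mask(
            ls, spec.base_axes_um, spec.pixel_size_um, spec.elongated_length_um
        )
        crops.append(_rotate_mask(base, float(nrng.uniform(0, 180))))

    in_tube = truth["in_myotube"].to_numpy()
    n_myo = int(in_tube.sum())
    tube_ranges: list[tuple[int, int]] = []
    tube_plane = None
    if n_myo > 0:
        n_tubes = max(1, n_myo // 4)
        while n_tubes > 1 and n_myo / n_tubes < 2:
            n_tubes -= 1
        tube_crop_h = max(
            (crops[i].shape[0] for i in range(len(crops)) if in_tube[i]), default=0
        )
        band_h_px = max(
            int(2.4 * spec.base_axes_um[1] / spec.pixel_size_um), tube_crop_h + 6
        )
        while n_tubes > 1 and n_tubes * band_h_px > 0.7 * shape_2d[0]:
            n_tubes -= 1
        tube_plane, tube_ranges = _make_tube_bands(spec, shape_2d, n_tubes, band_h_px)

    prng = np.random.default_rng([spec.seed, STREAM_PLACE])
    offsets, tube_ids = _placement_for(spec, crops, in_tube, tube_ranges, shape_2d, prng)
    truth["tube_id"] = tube_ids
    counts = pd.Series(tube_ids).value_counts()
    truth["in_myotube"] = [t > 0 and counts[t] >= 2 for t in tube_ids]

    # z semi-extent: roughly round nuclei, but never thicker than 80% of the
    # stack so nuclei keep clear of the z borders
    c_um = min(spec.base_axes_um[1] / 2.0, 0.4 * nz * spec.z_step_um)
    z_centers = nz / 2.0
    label_image = np.zeros(spec.field_size, dtype=np.int32)
    dna = np.zeros(spec.field_size)
    lamin_ac = np.zeros(spec.field_size)
    lamin_b1 = np.zeros(spec.field_size)
    emerin = np.zeros(spec.field_size)
    rim_ac = spec.rim_ratio * spec.nucleoplasm_level

    centroids = []
    for i, (crop, (row, col)) in enumerate(zip(crops, offsets)):
        dt = ndi.distance_transform_edt(crop)
        b_px = spec.base_axes_um[1] / 2.0 / spec.pixel_size_um
        r = truth.iloc[i]
        nrng = np.random.default_rng([spec.seed, STREAM_NUCLEUS, i, 1])
        feats = _nucleus_features(crop, spec, nrng)
        sl2 = (slice(row, row + crop.shape[0]), slice(col, col + crop.shape[1]))
        for z in range(nz):
            dz_um = (z - z_centers + 0.5) * spec.z_step_um
            if abs(dz_um) >= c_um:
                continue
            s = math.sqrt(max(0.0, 1.0 - (dz_um / c_um) ** 2))
            plane_mask = dt >= (1.0 - s) * b_px
            if not plane_mask.any():
                continue
            label_image[z][sl2][plane_mask] = i + 1
            dna[z][sl2][plane_mask] = spec.dna_level
            lamin_ac[z][sl2] += _lamin_plane(
                plane_mask, spec, rim_ac, feats,
                honeycomb=bool(r["has_honeycomb"]), foci=bool(r["has_foci"]),
                capping=False,
            )
            lamin_b1[z][sl2] += _lamin_plane(
                plane_mask, spec, 1.3 * spec.nucleoplasm_level, feats,
                honeycomb=False, foci=False,
                capping=bool(r["has_capping"]),
            )
            emerin[z][sl2] += _lamin_plane(
                plane_mask, spec, 1.4 * spec.nucleoplasm_level, feats,
                honeycomb=False, foci=bool(r["has_emerin_foci"]),
                capping=False,
            )
        czyx = np.argwhere(label_image == i + 1).mean(axis=0)
        centroids.append(czyx)

    truth["centroid_plane"] = [c[0] for c in centroids]
    truth["centroid_row"] = [c[1] for c in centroids]
    truth["centroid_col"] = [c[2] for c in centroids]

    channels = {"dna": dna, "lamin_ac": lamin_ac, "lamin_b1": lamin_b1, "emerin": emerin}
    tube_label_image = None
    if tube_plane is not None:
        tube_label_image = np.broadcast_to(tube_plane, spec.field_size).copy()
        myhc = np.where(tube_label_image > 0, spec.myhc_level, 0.0)
        myhc[label_image > 0] *= spec.myhc_nuclear_exclusion
        channels["myhc"] = myhc

    xrng = np.random.default_rng([spec.seed, 0x0153])
    for role in channels:
        channels[role] = _apply_noise(channels[role], spec, xrng)

    field = ImageField(
        channels=channels, pixel_size_um=spec.pixel_size_um, z_step_um=spec.z_step_um
    )
    return field, GroundTruth(truth, label_image, tube_label_image)


def write_phantom(out_dir: str | Path, field: ImageField, truth: GroundTruth, spec: PhantomSpec) -> None:
    """Write a phantom as TIFF channels + ground-truth CSV + spec JSON."""
    from .io import write_field  # deferred to avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_field(out / "field.tif", field)
    truth.table.to_csv(out / "ground_truth.csv", index=False)
    (out / "spec.json").write_text(spec.to_json())
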