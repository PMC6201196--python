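"""End-to-end orchestration: field(s) in, per-nucleus table + stats out."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import PipelineConfig, read_field
from .localization import LocalizationConfig, localize_nucleus
from .morphometry import ClassifierConfig, classify_shape, compute_shape_metrics
from .myotube import MyotubeConfig, assign_field
from .segmentation import (
    SegmentationConfig,
    measure_nucleus,
    segment_nuclei_2d,
    segment_nuclei_3d,
)
from .types import SHAPE_LABELS, ImageField, NucleusMask, PipelineError

logger = logging.getLogger(__name__)


def _footprint_2d(nucleus: NucleusMask) -> NucleusMask:
    """Mid-plane footprint of a 3D nucleus for 2D shape operators."""
    return NucleusMask(
        label_id=nucleus.label_id,
        mask=nucleus.mask.any(axis=0),
        offset=nucleus.offset[1:],
        pixel_size_um=nucleus.pixel_size_um,
        touches_border=nucleus.touches_border,
    )


def analyze_field(
    field: ImageField,
    seg_config: Optional[SegmentationConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
    loc_config: Optional[LocalizationConfig] = None,
    myo_config: Optional[MyotubeConfig] = None,
    marker_role: str = "myhc",
) -> pd.DataFrame:
    """Segment, measure, classify, localize and assign one field.

    Returns one row per segmented nucleus.  Border-touching nuclei are kept
    in the table with ``touches_border=True``; downstream aggregation
    excludes them.  For 3D stacks the shape operators run on the mid-plane
    footprint while the elongation rule uses the 3D principal-axis length.
    """
    cc = classifier_config or ClassifierConfig()
    if field.is_3d:
        nuclei = segment_nuclei_3d(field, config=seg_config)
    else:
        nuclei = segment_nuclei_2d(field, config=seg_config)
    logger.info("%s: %d nuclei segmented", field.field_id, len(nuclei))

    rows = []
    for nuc in nuclei:
        rec = measure_nucleus(nuc)
        nuc2d = _footprint_2d(nuc) if nuc.is_3d else nuc
        metrics = compute_shape_metrics(nuc2d, cc)
        if nuc.is_3d:
            # elongation uses the 3D length; 2D operators use the footprint
            metrics.major_axis_um = rec["major_axis_um"]
            rec["area_um2"] = nuc2d.area_um2
            rec["perimeter_um"] = metrics.perimeter_um
        labels = classify_shape(nuc2d, metrics, cc)
        rec["contour_ratio"] = metrics.contour_ratio
        rec["solidity"] = metrics.solidity
        rec["in_normal_cr_band"] = metrics.in_normal_cr_band
        for name in SHAPE_LABELS:
            rec[f"label_{name}"] = name in labels
        rec["is_normal"] = labels.is_normal
        rec["labels"] = "+".join(labels)
        rec.update(localize_nucleus(field, nuc, loc_config))
        rows.append(rec)

    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    assignments = assign_field(field, nuclei, marker_role, myo_config)
    amap = {a.label_id: a for a in assignments}
    df["in_myotube"] = [amap[i].in_myotube for i in df["label_id"]]
    df["structure_id"] = [
        amap[i].structure_id if amap[i].structure_id is not None else -1
        for i in df["label_id"]
    ]
    df.insert(0, "field_id", field.field_id)
    return df


def run_pipeline(
    paths: Sequence[str | Path],
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Run the full pipeline over TIFF files and write the per-nucleus CSV.

    Each input file becomes one field; the config's line/condition/repeat
    identifiers are attached to every row.  Deterministic for fixed inputs.
    """
    cfg = config or PipelineConfig()
    paths = list(paths)
    if not paths:
        raise PipelineError("no input files")
    seg = SegmentationConfig(**cfg.segmentation) if cfg.segmentation else None
    cls = ClassifierConfig(**cfg.classifier) if cfg.classifier else None
    loc = LocalizationConfig(**cfg.localization) if cfg.localization else None
    myo = MyotubeConfig(**cfg.myotube) if cfg.myotube else None

    tables = []
    for p in paths:
        try:
            field = read_field(p, cfg)
        except Exception as e:
            raise PipelineError(f"read stage failed on {p}: {e}") from e
        try:
            tables.append(analyze_field(field, seg, cls, loc, myo))
        except Exception as e:
            raise PipelineError(f"analysis stage failed on {p}: {e}") from e
    df = pd.concat([t for t in tables if len(t)], ignore_index=True) if tables else pd.DataFrame()
    if len(df):
        df["line_id"] = cfg.line_id
        df["condition"] = cfg.condition
        df["repeat_id"] = cfg.repeat_id
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "nuclei.csv", index=False)
        n_border = int(df["touches_border"].sum()) if len(df) else 0
        logger.info(
            "pipeline: %d fields, %d nuclei (%d border-excluded)",
            len(paths), len(df), n_border,
        )
    return df
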