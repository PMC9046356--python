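"""Stage orchestration shared by the CLI, tests and acceptance script.

Each stage is a plain function over in-memory objects; the CLI adds disk
artifacts and manifests around them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import (
    LayerAnnotation,
    assign_layers,
    build_cell_table,
    summarize_by_layer,
    surface_density,
)
from .segmentation import SegmentationParams, segment_image
from .synthetic import SpecimenDataset, Study, analytic_cell_table

__all__ = ["annotation_for", "measure_specimen", "measure_study", "summarize_study"]


def annotation_for(specimen: SpecimenDataset) -> LayerAnnotation:
    """Flat laminar annotation matching the generator's band geometry."""
    return LayerAnnotation.from_depths(
        specimen.layer_boundaries,
        x_range=(0.0, specimen.truth.strip_width_um),
    )


def measure_specimen(
    specimen: SpecimenDataset,
    use_truth: bool = True,
    seg_params: SegmentationParams = SegmentationParams(),
    radius_um: float = 50.0,
) -> pd.DataFrame:
    """Per-cell table for one specimen.

    ``use_truth=True`` bypasses segmentation and computes descriptors in
    closed form from the generating ellipses (what a perfect segmentation
    would measure); otherwise the rendered image is segmented.
    """
    annotation = annotation_for(specimen)
    if use_truth:
        df = analytic_cell_table(specimen.truth)
        df["density_50um"] = surface_density(
            df[["x_um", "y_um"]].to_numpy(), radius_um
        )
        df["layer"] = assign_layers(df[["x_um", "y_um"]].to_numpy(), annotation)
        df.insert(0, "specimen_id", specimen.specimen_id)
        return df
    if specimen.image is None:
        raise ValueError(
            f"specimen {specimen.specimen_id}: no image rendered and truth "
            f"bypass disabled"
        )
    records = segment_image(specimen.image, specimen.pixel_size, seg_params)
    return build_cell_table(
        records, annotation, radius_um, specimen_id=specimen.specimen_id
    )


def measure_study(
    study: Study,
    use_truth: bool = True,
    seg_params: SegmentationParams = SegmentationParams(),
    radius_um: float = 50.0,
) -> pd.DataFrame:
    """Concatenated cell tables of every specimen in the study."""
    return pd.concat(
        [measure_specimen(s, use_truth, seg_params, radius_um) for s in study],
        ignore_index=True,
    )


def summarize_study(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen per-layer medians (the observation matrix rows for
    group inference)."""
    frames = []
    for sid, grp in cells.groupby("specimen_id", sort=True):
        summ = summarize_by_layer(grp)
        summ.insert(0, "specimen_id", sid)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)
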