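"""Per-cell morphometry, laminar assignment and cortical thickness.

Descriptors follow the three analysis domains: size (area, perimeter),
shape (circularity, solidity, extent, inverse aspect ratio, eccentricity)
and density (number of neighbouring cells within a 50 µm radius, the raw
2-D surface density with no edge correction and the cell itself excluded).
All linear outputs are in µm / µm² except cortical thickness, reported in
mm by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from skimage.measure import perimeter_crofton as _perimeter
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .segmentation import CellRecord

__all__ = [
    "DescriptorVector",
    "LayerAnnotation",
    "ThicknessMeasurement",
    "compute_descriptors",
    "surface_density",
    "assign_layers",
    "measure_cortical_thickness",
    "summarize_by_layer",
    "build_cell_table",
    "DESCRIPTOR_COLUMNS",
]

#: Descriptor columns of a cell table, in canonical order.
DESCRIPTOR_COLUMNS = (
    "area_um2",
    "perimeter_um",
    "circularity",
    "solidity",
    "extent",
    "inv_ar",
    "eccentricity",
)


@dataclass(frozen=True)
class DescriptorVector:
    area_um2: float
    perimeter_um: float
    circularity: float  # 4*pi*area/perimeter^2, 1 for a disc
    solidity: float  # area / convex hull area
    extent: float  # area / bounding-box area
    inv_ar: float  # minor/major axis of the best-fit ellipse
    eccentricity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_descriptors(footprint: np.ndarray, pixel_size: float) -> DescriptorVector:
    """Size and shape descriptors of a single connected raster footprint.

    Area is pixel count × pixel_size²; perimeter uses the Crofton formula
    over 4 directions, whose bias for convex rasterised shapes is about 1%
    (the simpler √2-weighted boundary-step estimator overestimates disc
    perimeters by ~3% and was rejected against the closed forms);
    solidity uses the pixelised convex hull; the ellipse-based descriptors
    come from the second-moment best-fit ellipse.  Footprints under 3 px
    are rejected — their descriptors are undefined.
    """
    fp = np.asarray(footprint, dtype=bool)
    n_px = int(fp.sum())
    if n_px < 3:
        raise ValueError("footprint must contain at least 3 pixels")
    if _cc_label(fp, connectivity=2).max() != 1:
        raise ValueError("footprint must be a single connected component")
    region = regionprops(fp.astype(np.uint8))[0]
    area = n_px * pixel_size**2
    perim = _perimeter(fp, directions=4) * pixel_size
    major = region.axis_major_length
    minor = region.axis_minor_length
    inv_ar = float(minor / major) if major > 0 else 1.0
    return DescriptorVector(
        area_um2=float(area),
        perimeter_um=float(perim),
        circularity=float(4 * np.pi * area / perim**2) if perim > 0 else np.nan,
        solidity=float(region.solidity),
        extent=float(region.extent),
        inv_ar=inv_ar,
        eccentricity=float(region.eccentricity),
    )


def surface_density(points_um: np.ndarray, radius_um: float = 50.0) -> np.ndarray:
    """Number of *other* cell centroids within ``radius_um`` of each cell.

    Raw 2-D count, self excluded (an isolated cell scores 0), no edge
    correction: cells near the strip border keep their censored count.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius_um, return_length=True)
    return np.asarray(counts, dtype=int) - 1


class LayerAnnotation:
    """Ordered laminar boundaries in µm: pial surface first, then L1/L2 …
    L6/white matter.  Each boundary is a polyline ``(x_um, depth_um)`` or a
    scalar depth (flat band).  Boundaries must be depth-ordered and
    non-crossing within the strip."""

    def __init__(
        self,
        boundaries: list,
        layer_names: list[str] | None = None,
        x_range: tuple[float, float] = (0.0, 2000.0),
    ) -> None:
        polys = []
        for b in boundaries:
            if np.isscalar(b):
                polys.append(
                    np.array([[x_range[0], float(b)], [x_range[1], float(b)]])
                )
            else:
                arr = np.asarray(b, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
                    raise ValueError("boundary polylines need shape (m>=2, 2)")
                polys.append(arr[np.argsort(arr[:, 0])])
        if len(polys) < 2:
            raise ValueError("need at least two boundaries (pial and deep)")
        self.boundaries = polys
        n_layers = len(polys) - 1
        self.layer_names = (
            list(layer_names)
            if layer_names is not None
            else [f"L{i + 1}" for i in range(n_layers)]
        )
        if len(self.layer_names) != n_layers:
            raise ValueError("layer_names must have len(boundaries) - 1 entries")
        xs = np.unique(np.concatenate([p[:, 0] for p in polys]))
        depth = np.stack([self.depth_at(k, xs) for k in range(len(polys))])
        if np.any(np.diff(depth, axis=0) < -1e-9):
            raise ValueError("layer boundaries cross: malformed annotation")

    @classmethod
    def from_depths(
        cls, depths, layer_names=None, x_range=(0.0, 2000.0)
    ) -> "LayerAnnotation":
        return cls([float(d) for d in depths], layer_names, x_range)

    def depth_at(self, k: int, x) -> np.ndarray:
        p = self.boundaries[k]
        return np.interp(np.asarray(x, dtype=float), p[:, 0], p[:, 1])

    def to_json_dict(self) -> dict:
        return {
            "layer_names": self.layer_names,
            "boundaries_um": [p.tolist() for p in self.boundaries],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LayerAnnotation":
        return cls([np.asarray(p) for p in d["boundaries_um"]], d["layer_names"])


def assign_layers(points_um: np.ndarray, annotation: LayerAnnotation) -> np.ndarray:
    """Laminar label per centroid; band membership is half-open in depth so
    a centroid exactly on a boundary goes to the *deeper* layer.  Points
    above the pial surface or at/below the deepest boundary are labelled
    ``"unassigned"`` (and should be excluded downstream)."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    labels = np.full(len(pts), "unassigned", dtype=object)
    if len(pts) == 0:
        return labels
    depths = np.stack(
        [annotation.depth_at(k, pts[:, 0]) for k in range(len(annotation.boundaries))]
    )
    d = pts[:, 1]
    for li, name in enumerate(annotation.layer_names):
        inside = (d >= depths[li]) & (d < depths[li + 1])
        labels[inside] = name
    return labels


@dataclass(frozen=True)
class ThicknessMeasurement:
    """Cortical thickness at ≥ 5 sites, in mm (per-site values, mean, sd)."""

    sites_mm: np.ndarray
    mean_mm: float
    sd_mm: float

    @property
    def n_sites(self) -> int:
        return len(self.sites_mm)


def measure_cortical_thickness(
    annotation: LayerAnnotation,
    sites_x_um,
    min_valid_sites: int = 5,
) -> ThicknessMeasurement:
    """Thickness measured along the local normal of the pial surface.

    At each site the pial polyline's local tangent defines a normal ray
    into the cortex; thickness is the distance along that ray to the
    deepest boundary (L6/white matter).  This is the length perpendicular
    to a line placed on the pial surface — for a tilted deep boundary the
    measurement is the separation along the pial normal, not the
    perpendicular distance to the deep boundary.  Sites whose normal never
    meets the deep boundary are skipped with a warning; fewer than
    ``min_valid_sites`` valid sites is an error.
    """
    sites = np.atleast_1d(np.asarray(sites_x_um, dtype=float))
    if len(sites) < min_valid_sites:
        raise ValueError(f"need at least {min_valid_sites} measurement sites")
    pial = annotation.boundaries[0]
    deep = annotation.boundaries[-1]
    deep_line = LineString(deep)
    span = float(deep[:, 1].max() - pial[:, 1].min()) + float(
        np.ptp(pial[:, 0]) + np.ptp(deep[:, 0])
    )
    values = []
    for x in sites:
        y0 = float(annotation.depth_at(0, x))
        eps = max(np.ptp(pial[:, 0]) * 1e-4, 1e-6)
        slope = (
            float(annotation.depth_at(0, x + eps)) - float(annotation.depth_at(0, x - eps))
        ) / (2 * eps)
        n = np.array([-slope, 1.0]) / np.hypot(slope, 1.0)  # into the cortex
        ray = LineString([(x, y0), (x + span * 2 * n[0], y0 + span * 2 * n[1])])
        hit = ray.intersection(deep_line)
        if hit.is_empty:
            warnings.warn(f"site x={x:g} µm: pial normal misses the deep boundary")
            continue
        p0 = np.array([x, y0])
        pts = (
            [np.array(g.coords[0]) for g in hit.geoms]
            if hasattr(hit, "geoms")
            else [np.array(hit.coords[0])]
        )
        values.append(min(np.linalg.norm(p - p0) for p in pts))
    if len(values) < min_valid_sites:
        raise ValueError(
            f"only {len(values)} valid thickness sites (need {min_valid_sites})"
        )
    vals_mm = np.asarray(values) / 1000.0
    sd = float(np.std(vals_mm, ddof=1)) if len(vals_mm) > 1 else 0.0
    return ThicknessMeasurement(vals_mm, float(vals_mm.mean()), sd)


def build_cell_table(
    records: list[CellRecord],
    annotation: LayerAnnotation | None = None,
    radius_um: float = 50.0,
    specimen_id: str | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell table from segmentation records: descriptors,
    50 µm surface density, laminar labels and the border flag."""
    rows = []
    for rec in records:
        desc = compute_descriptors(rec.footprint, rec.pixel_size)
        rows.append(
            {
                "x_um": rec.x_um,
                "y_um": rec.y_um,
                **desc.as_dict(),
                "border_flag": rec.border,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["x_um", "y_um", *DESCRIPTOR_COLUMNS, "border_flag"],
    )
    df["density_50um"] = surface_density(
        df[["x_um", "y_um"]].to_numpy(), radius_um
    ) if len(df) else np.zeros(0, dtype=int)
    if annotation is not None:
        df["layer"] = assign_layers(df[["x_um", "y_um"]].to_numpy(), annotation)
    if specimen_id is not None:
        df.insert(0, "specimen_id", specimen_id)
    return df


def summarize_by_layer(
    cells: pd.DataFrame,
    variables: tuple[str, ...] = (*DESCRIPTOR_COLUMNS, "density_50um"),
) -> pd.DataFrame:
    """Per-layer medians with (25th, 75th) percentile dispersion.

    Size/shape descriptors are censored for border-flagged cells (their
    footprints are clipped by the frame); the density count keeps every
    cell.  Layers with no assigned cells are simply absent from the output
    (missing, not zero).  Row order of the input is irrelevant.
    """
    df = cells[cells["layer"] != "unassigned"] if "layer" in cells else cells.copy()
    out_rows = []
    for layer, grp in sorted(df.groupby("layer"), key=lambda kv: kv[0]):
        row: dict[str, object] = {"layer": layer, "n_cells": len(grp)}
        interior = (
            grp[~grp["border_flag"].astype(bool)] if "border_flag" in grp else grp
        )
        for var in variables:
            src = grp if var == "density_50um" else interior
            vals = src[var].dropna()
            if len(vals) == 0:
                row[var] = np.nan
                row[f"{var}_q25"] = np.nan
                row[f"{var}_q75"] = np.nan
            else:
                row[var] = float(vals.median())
                row[f"{var}_q25"] = float(vals.quantile(0.25))
                row[f"{var}_q75"] = float(vals.quantile(0.75))
        out_rows.append(row)
    return pd.DataFrame(out_rows)
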