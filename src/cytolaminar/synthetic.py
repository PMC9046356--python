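"""Synthetic cortical-column generator.

Produces specimen-level cell populations (a hard-core planar point pattern of
ellipses, stratified into six flat laminar bands) and, optionally, rendered
Nissl-like grayscale images with calibration.  The generator carries its own
ground truth so every downstream stage — thresholding, centre detection,
morphometry, group inference — can be scored against known cells without any
histological material.

Layer structure
---------------
Each layer is parameterised by a thickness, an expected cell density
(cells/mm²), a lognormal cell-area distribution (µm²) and a minor/major
axis-ratio distribution.  Group effects multiply density and size per layer
and may inflate dispersion (a group-specific scale effect); specimen effects
are lognormal multipliers shared by all cells of one specimen, so that when
all group effects are the identity the specimens are exchangeable across
groups — the null hypothesis downstream tests are calibrated against.

Sections are thin (5 µm in the emulated protocol) so cell somata do not
overlap: the point pattern is hard-core, with inter-centroid distance at
least the sum of the two semi-minor axes, enforced by dart throwing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "LayerParams",
    "GroupEffect",
    "SyntheticTruth",
    "SpecimenDataset",
    "Study",
    "DEFAULT_LAYERS",
    "sample_layer_population",
    "render_nissl_image",
    "generate_group_study",
    "analytic_cell_table",
]


class SimulationError(RuntimeError):
    """Raised when a requested point pattern cannot be realised."""


@dataclass(frozen=True)
class LayerParams:
    """Generative parameters of one cortical layer.

    Parameters
    ----------
    layer_id:
        Label, conventionally one of ``L1`` .. ``L6``.
    thickness_um:
        Band thickness in µm, > 0.
    density_per_mm2:
        Expected cell count per mm² of section, ≥ 0.
    area_log_mean, area_log_sd:
        Parameters of the lognormal soma-area distribution (area in µm²);
        the median area is ``exp(area_log_mean)``.
    axis_ratio_mean, axis_ratio_sd:
        Mean/sd of the minor/major axis ratio; samples are clipped to (0, 1].
    orientation_concentration:
        Von Mises concentration of the major-axis orientation around the
        radial (depth) axis; 0 means isotropic.
    """

    layer_id: str
    thickness_um: float
    density_per_mm2: float
    area_log_mean: float
    area_log_sd: float
    axis_ratio_mean: float = 0.75
    axis_ratio_sd: float = 0.10
    orientation_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.layer_id}: thickness must be > 0")
        if self.density_per_mm2 < 0:
            raise ValueError(f"layer {self.layer_id}: density must be >= 0")
        if self.area_log_sd < 0 or self.axis_ratio_sd < 0:
            raise ValueError(f"layer {self.layer_id}: dispersions must be >= 0")
        if self.orientation_concentration < 0:
            raise ValueError(f"layer {self.layer_id}: concentration must be >= 0")


#: Default six-layer parameter table for the synthetic column.  Densities and
#: median soma areas follow the canonical laminar pattern of a sensory cortex
#: (dense small granule cells in L2/L4, sparse large pyramidal somata in L5);
#: magnitudes are generator conventions chosen to be realistic for Nissl
#: sections, not measurements.
DEFAULT_LAYERS: tuple[LayerParams, ...] = (
    LayerParams("L1", 150.0, 250.0, math.log(40.0), 0.35),
    LayerParams("L2", 200.0, 800.0, math.log(55.0), 0.35),
    LayerParams("L3", 350.0, 550.0, math.log(95.0), 0.35),
    LayerParams("L4", 200.0, 800.0, math.log(50.0), 0.35),
    LayerParams("L5", 300.0, 400.0, math.log(150.0), 0.35),
    LayerParams("L6", 300.0, 550.0, math.log(85.0), 0.35),
)


@dataclass(frozen=True)
class GroupEffect:
    """Group-level effects: location multipliers on density and size, and a
    scale multiplier inflating within-group dispersion.

    ``density_multiplier`` / ``size_multiplier`` may be scalars or mappings
    ``layer_id -> multiplier``; ``scale_multiplier`` is a scalar applied to
    the lognormal sd of cell area and to the axis-ratio sd.
    """

    group_id: str
    density_multiplier: float | Mapping[str, float] = 1.0
    size_multiplier: float | Mapping[str, float] = 1.0
    scale_multiplier: float = 1.0
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("density_multiplier", "size_multiplier"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, Mapping) else (val,)
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be > 0")
        if self.scale_multiplier <= 0:
            raise ValueError("scale_multiplier must be > 0")

    def density_for(self, layer_id: str) -> float:
        if isinstance(self.density_multiplier, Mapping):
            return float(self.density_multiplier.get(layer_id, 1.0))
        return float(self.density_multiplier)

    def size_for(self, layer_id: str) -> float:
        if isinstance(self.size_multiplier, Mapping):
            return float(self.size_multiplier.get(layer_id, 1.0))
        return float(self.size_multiplier)


IDENTITY_EFFECT = GroupEffect("identity")

#: Columns of a truth cell table, one row per generated cell.
TRUTH_COLUMNS = ("x_um", "y_um", "major_um", "minor_um", "theta_rad", "layer")


@dataclass
class SyntheticTruth:
    """Ground-truth cell population of one synthetic specimen strip.

    ``cells`` has columns ``x_um`` (lateral position), ``y_um`` (depth from
    the pial surface), full ``major_um``/``minor_um`` ellipse axis lengths,
    ``theta_rad`` (major-axis angle from the lateral axis) and ``layer``.
    ``layer_boundaries`` are the 7 band edges in depth (pial surface first).
    """

    cells: pd.DataFrame
    layer_boundaries: np.ndarray
    strip_width_um: float
    pixel_size: float
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        """Check the structural invariants: centroids inside their band and
        the hard-core (non-overlap) constraint on every pair."""
        b = np.asarray(self.layer_boundaries, dtype=float)
        depths = self.cells["y_um"].to_numpy()
        layer_idx = self.cells["layer"].map(
            {f"L{i + 1}": i for i in range(len(b) - 1)}
        ).to_numpy()
        lo, hi = b[layer_idx], b[layer_idx + 1]
        if not np.all((depths >= lo) & (depths <= hi)):
            raise AssertionError("cell centroid outside its layer band")
        xy = self.cells[["x_um", "y_um"]].to_numpy()
        semi_minor = self.cells["minor_um"].to_numpy() / 2.0
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        lim = semi_minor[:, None] + semi_minor[None, :]
        np.fill_diagonal(d, np.inf)
        if not np.all(d >= lim - 1e-9):
            raise AssertionError("hard-core constraint violated")


def _sample_ellipses(
    n: int,
    params: LayerParams,
    size_mult: float,
    scale_mult: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``n`` (major, minor, theta) triples (full axis lengths, µm)."""
    area = rng.lognormal(
        params.area_log_mean + math.log(size_mult),
        params.area_log_sd * scale_mult,
        size=n,
    )
    ratio = rng.normal(params.axis_ratio_mean, params.axis_ratio_sd * scale_mult, n)
    ratio = np.clip(ratio, 0.05, 1.0)
    semi_major = np.sqrt(area / (np.pi * ratio))
    semi_minor = semi_major * ratio
    if params.orientation_concentration > 0:
        theta = rng.vonmises(np.pi / 2, params.orientation_concentration, n) % np.pi
    else:
        theta = rng.uniform(0.0, np.pi, n)
    return 2 * semi_major, 2 * semi_minor, theta


def sample_layer_population(
    params: LayerParams,
    effect: GroupEffect = IDENTITY_EFFECT,
    strip_width_um: float = 2000.0,
    rng: np.random.Generator | int | None = None,
    *,
    depth_top_um: float = 0.0,
    specimen_density_mult: float = 1.0,
    specimen_size_mult: float = 1.0,
    existing: pd.DataFrame | None = None,
    max_oversample: int = 50,
) -> pd.DataFrame:
    """Sample one layer's cells as a hard-core point pattern.

    The target count is Poisson with mean ``density × multipliers × area``;
    candidate centres are darted uniformly into the band and accepted when
    their distance to every previously accepted centre (including cells in
    ``existing``, e.g. adjacent layers of the same specimen) is at least the
    sum of the two semi-minor axes.  At most ``max_oversample`` candidates
    per target cell are drawn; running out raises :class:`SimulationError`
    naming the layer (density too high for the hard-core constraint).
    """
    if strip_width_um <= 0:
        raise ValueError("strip_width_um must be > 0")
    rng = np.random.default_rng(rng)
    lam = (
        params.density_per_mm2
        * effect.density_for(params.layer_id)
        * specimen_density_mult
        * (strip_width_um / 1000.0)
        * (params.thickness_um / 1000.0)
    )
    n_target = int(rng.poisson(lam)) if lam > 0 else 0
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TRUTH_COLUMNS, (float, float, float, float, float, str))})
    if n_target == 0:
        return empty

    size_mult = effect.size_for(params.layer_id) * specimen_size_mult
    if existing is not None and len(existing):
        acc_xy = [existing[["x_um", "y_um"]].to_numpy()]
        acc_b = [existing["minor_um"].to_numpy() / 2.0]
    else:
        acc_xy, acc_b = [], []
    n_prior = sum(len(a) for a in acc_b)

    out_rows: list[tuple] = []
    budget = max_oversample * n_target
    drawn = 0
    # dart throwing in batches; each accepted candidate immediately becomes
    # an obstacle for the rest of its batch (sequential check)
    while len(out_rows) < n_target and drawn < budget:
        batch = min(n_target - len(out_rows), budget - drawn, 256)
        xs = rng.uniform(0.0, strip_width_um, batch)
        ys = rng.uniform(depth_top_um, depth_top_um + params.thickness_um, batch)
        majors, minors, thetas = _sample_ellipses(
            batch, params, size_mult, effect.scale_multiplier, rng
        )
        drawn += batch
        flat_xy = np.concatenate(acc_xy) if acc_xy else np.empty((0, 2))
        flat_b = np.concatenate(acc_b) if acc_b else np.empty(0)
        for i in range(batch):
            b = minors[i] / 2.0
            if len(flat_xy):
                d = np.hypot(flat_xy[:, 0] - xs[i], flat_xy[:, 1] - ys[i])
                if np.any(d < flat_b + b):
                    continue
            flat_xy = np.vstack([flat_xy, (xs[i], ys[i])])
            flat_b = np.append(flat_b, b)
            out_rows.append((xs[i], ys[i], majors[i], minors[i], thetas[i]))
        acc_xy, acc_b = [flat_xy], [flat_b]

    if len(out_rows) < n_target:
        raise SimulationError(
            f"layer {params.layer_id}: placed {len(out_rows)}/{n_target} cells "
            f"after {drawn} candidates — density too high for the hard-core "
            f"constraint"
        )
    df = pd.DataFrame(out_rows, columns=list(TRUTH_COLUMNS[:-1]))
    df["layer"] = params.layer_id
    return df


def render_nissl_image(
    truth: SyntheticTruth,
    noise_sd: float = 6.0,
    illumination_gradient: float = 0.0,
    *,
    background: float = 200.0,
    foreground: float = 90.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a truth population as a grayscale image (float, arbitrary
    intensity units) plus a calibration dict.

    Cells are dark ellipses on a brighter background (thionine polarity).
    A linear illumination field (``illumination_gradient`` intensity units
    per mm of depth) and additive Gaussian noise are applied to the whole
    composited image, so cell/background contrast is depth-invariant while
    any single global threshold is not.
    """
    ps = truth.pixel_size
    if ps <= 0:
        raise ValueError("pixel_size must be > 0")
    if truth.n_cells and float(np.median(truth.cells["minor_um"])) / ps < 3.0:
        raise ValueError(
            "pixel size too coarse: median cell diameter below 3 px — cells "
            "are unresolvable at this calibration"
        )
    height_um = float(truth.layer_boundaries[-1])
    h = int(math.ceil(height_um / ps))
    w = int(math.ceil(truth.strip_width_um / ps))
    img = np.full((h, w), background, dtype=float)
    for row in truth.cells.itertuples(index=False):
        rr, cc = _draw_ellipse(
            row.y_um / ps,
            row.x_um / ps,
            row.minor_um / 2.0 / ps,
            row.major_um / 2.0 / ps,
            shape=img.shape,
            rotation=row.theta_rad,
        )
        img[rr, cc] = foreground
    if illumination_gradient != 0.0:
        depth_mm = (np.arange(h) + 0.5) * ps / 1000.0
        img += illumination_gradient * depth_mm[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng((truth.seed, 7)) if rng is None else rng
        img += rng.normal(0.0, noise_sd, img.shape)
    calibration = {
        "pixel_size_um": ps,
        "strip_width_um": truth.strip_width_um,
        "depth_um": height_um,
        "polarity": "dark_cells",
    }
    return img, calibration


@dataclass
class SpecimenDataset:
    """All data of one specimen: truth table, calibration, laminar geometry
    and group metadata (plus the rendered image when requested)."""

    specimen_id: str
    group: str
    truth: SyntheticTruth
    metadata: dict = field(default_factory=dict)
    image: np.ndarray | None = None
    calibration: dict | None = None

    @property
    def layer_boundaries(self) -> np.ndarray:
        return self.truth.layer_boundaries

    @property
    def pixel_size(self) -> float:
        return self.truth.pixel_size


@dataclass
class Study:
    """A set of specimens plus the design table mapping them to groups."""

    specimens: list[SpecimenDataset]
    design: pd.DataFrame  # one row per specimen: specimen_id, group, metadata

    def __iter__(self):
        return iter(self.specimens)


def _specimen_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_group_study(
    effects: Sequence[GroupEffect],
    n_specimens_per_group: int | Mapping[str, int],
    *,
    seed: int,
    layer_params: Sequence[LayerParams] = DEFAULT_LAYERS,
    strip_width_um: float = 2000.0,
    pixel_size: float = 1.0,
    specimen_sd: float = 0.05,
    render: bool = False,
    noise_sd: float = 6.0,
    illumination_gradient: float = 0.0,
) -> Study:
    """Generate a multi-group study of synthetic specimens.

    Each specimen receives lognormal random multipliers (sd ``specimen_sd``)
    on density and size, shared across its layers, on top of its group's
    effects; with identity effects the groups are exchangeable.  Randomness
    is derived from ``seed`` through spawned generators, so output is
    deterministic and independent of evaluation order.
    """
    if not effects:
        raise ValueError("at least one group is required")
    boundaries = np.concatenate(
        [[0.0], np.cumsum([lp.thickness_um for lp in layer_params])]
    )
    root = np.random.SeedSequence(seed)
    specimens: list[SpecimenDataset] = []
    design_rows = []
    children_idx = 0
    all_children = root.spawn(
        sum(
            (n_specimens_per_group[e.group_id]
             if isinstance(n_specimens_per_group, Mapping)
             else n_specimens_per_group)
            for e in effects
        )
    )
    for effect in effects:
        n = (
            n_specimens_per_group[effect.group_id]
            if isinstance(n_specimens_per_group, Mapping)
            else int(n_specimens_per_group)
        )
        if n < 1:
            raise ValueError(
                f"group {effect.group_id!r} needs at least 1 specimen"
            )
        for i in range(n):
            child = all_children[children_idx]
            children_idx += 1
            rng = np.random.default_rng(child)
            dens_mult = float(rng.lognormal(0.0, specimen_sd))
            size_mult = float(rng.lognormal(0.0, specimen_sd))
            frames: list[pd.DataFrame] = []
            for li, lp in enumerate(layer_params):
                prior = pd.concat(frames, ignore_index=True) if frames else None
                frames.append(
                    sample_layer_population(
                        lp,
                        effect,
                        strip_width_um,
                        rng,
                        depth_top_um=float(boundaries[li]),
                        specimen_density_mult=dens_mult,
                        specimen_size_mult=size_mult,
                        existing=prior,
                    )
                )
            cells = pd.concat(frames, ignore_index=True)
            truth = SyntheticTruth(
                cells=cells,
                layer_boundaries=boundaries.copy(),
                strip_width_um=strip_width_um,
                pixel_size=pixel_size,
                seed=_specimen_seed(child),
            )
            sid = f"{effect.group_id}_{i + 1:02d}"
            spec = SpecimenDataset(
                specimen_id=sid,
                group=effect.group_id,
                truth=truth,
                metadata=dict(effect.metadata),
            )
            if render:
                spec.image, spec.calibration = render_nissl_image(
                    truth,
                    noise_sd=noise_sd,
                    illumination_gradient=illumination_gradient,
                    rng=rng,
                )
            specimens.append(spec)
            design_rows.append(
                {"specimen_id": sid, "group": effect.group_id, **effect.metadata}
            )
    return Study(specimens=specimens, design=pd.DataFrame(design_rows))


def analytic_cell_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Closed-form morphometric descriptors of the truth ellipses.

    Used for the segmentation-free bypass: area/perimeter/shape descriptors
    are computed from the generating ellipse parameters (Ramanujan perimeter
    approximation; bounding box of the rotated ellipse for extent), which is
    what a perfect segmentation would measure up to rasterisation error.
    Surface density and layer labels are appended downstream.
    """
    c = truth.cells
    a = c["major_um"].to_numpy() / 2.0
    b = c["minor_um"].to_numpy() / 2.0
    theta = c["theta_rad"].to_numpy()
    area = np.pi * a * b
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    wx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    wy = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    ratio = b / a
    return pd.DataFrame(
        {
            "x_um": c["x_um"].to_numpy(),
            "y_um": c["y_um"].to_numpy(),
            "layer": c["layer"].to_numpy(),
            "area_um2": area,
            "perimeter_um": perim,
            "circularity": 4 * np.pi * area / perim**2,
            "solidity": np.ones_like(area),
            "extent": area / (4 * wx * wy),
            "inv_ar": ratio,
            "eccentricity": np.sqrt(1.0 - ratio**2),
            "border_flag": np.zeros(len(c), dtype=bool),
        }
    )
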