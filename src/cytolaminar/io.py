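"""Run configuration and on-disk artifacts.

Images are single-channel TIFFs with a JSON calibration sidecar; cell and
truth tables are CSV; configuration is one YAML file per run whose resolved
contents (defaults included) are serialized into every results bundle for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .inference import DOMAINS_DEFAULT, ModelSpec
from .segmentation import SegmentationParams
from .synthetic import GroupEffect


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int
    outdir: str
    groups: list[dict] = field(default_factory=list)
    n_specimens_per_group: int = 3
    strip_width_um: float = 2000.0
    pixel_size_um: float = 1.0
    specimen_sd: float = 0.05
    render: bool = False
    noise_sd: float = 6.0
    illumination_gradient: float = 20.0
    segmentation: dict = field(default_factory=dict)
    density_radius_um: float = 50.0
    use_truth_tables: bool = True
    grouping: str = "group"
    n_permutations: int = 999
    statistic: str = "location-scale"

    def effects(self) -> list[GroupEffect]:
        if not self.groups:
            raise ConfigError("config must declare at least one group")
        out = []
        for g in self.groups:
            if "id" not in g:
                raise ConfigError("every group needs an 'id'")
            out.append(
                GroupEffect(
                    group_id=str(g["id"]),
                    density_multiplier=g.get("density_multiplier", 1.0),
                    size_multiplier=g.get("size_multiplier", 1.0),
                    scale_multiplier=g.get("scale_multiplier", 1.0),
                    metadata=g.get("metadata", {}),
                )
            )
        return out

    def segmentation_params(self) -> SegmentationParams:
        try:
            return SegmentationParams(**self.segmentation)
        except TypeError as exc:
            raise ConfigError(f"bad segmentation parameters: {exc}") from exc

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            grouping=self.grouping,
            domains=dict(DOMAINS_DEFAULT),
            n_permutations=self.n_permutations,
            seed=self.seed,
            statistic=self.statistic,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit seed")
    if "outdir" not in raw:
        raise ConfigError("config must set outdir")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if not cfg.groups:
        raise ConfigError("config must declare at least one group")
    cfg.effects()  # validates group entries
    return cfg


def write_specimen(outdir: Path, specimen) -> list[Path]:
    """Write one specimen's artifacts (truth CSV, optional TIFF + sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    truth_path = outdir / f"{specimen.specimen_id}_truth.csv"
    specimen.truth.cells.to_csv(truth_path, index=False)
    written.append(truth_path)
    meta = {
        "specimen_id": specimen.specimen_id,
        "group": specimen.group,
        "pixel_size_um": specimen.pixel_size,
        "layer_boundaries_um": specimen.layer_boundaries.tolist(),
        "strip_width_um": specimen.truth.strip_width_um,
        "seed": specimen.truth.seed,
        **specimen.metadata,
    }
    if specimen.image is not None:
        img_path = outdir / f"{specimen.specimen_id}.tif"
        arr = np.clip(specimen.image, 0, 255).astype(np.uint8)
        tifffile.imwrite(img_path, arr)
        written.append(img_path)
        meta["calibration"] = specimen.calibration
    side = outdir / f"{specimen.specimen_id}.json"
    side.write_text(json.dumps(meta, indent=1))
    written.append(side)
    return written


def read_specimen_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(outdir: Path, cfg: RunConfig, files: list[Path]) -> Path:
    """Manifest with package version, resolved config + hash, and per-file
    SHA-256 digests — makes command outputs hash-stable and auditable."""
    outdir = Path(outdir)
    entries = {}
    for f in sorted(files, key=lambda p: Path(p).name):
        entries[Path(f).name] = hashlib.sha256(Path(f).read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "n_permutations": cfg.n_permutations,
        "files": entries,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
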