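"""File formats, configuration and provenance.

Monthly climatologies and parameter bundles travel as NetCDF (via xarray's
scipy backend, dimensions ``month, y, x``); single-band fields (production,
areas, masks, risk maps, category rasters) as single-page TIFF via
``tifffile``; tables as CSV; SCS definitions and provenance as JSON; run
configuration as YAML.  Grids are never resampled: every loader checks that
what it reads matches the reference grid and fails loudly, naming the
offending path, when it does not.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from . import __version__
from .climate import monthly_climatology
from .synthetic import WorldBundle, WorldConfig, generate_world

__all__ = [
    "save_field",
    "load_field",
    "save_monthly",
    "load_monthly",
    "save_params",
    "load_params",
    "load_align_rasters",
    "save_world",
    "load_world",
    "world_config_from_yaml",
    "ProvenanceRecord",
]


# ---------------------------------------------------------------------------
# single fields and monthly stacks


def save_field(field: xr.DataArray, path) -> None:
    """Write a 2-D field as a single-page TIFF (bool saved as uint8)."""
    values = field.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    tifffile.imwrite(str(path), values)


def load_field(path, as_bool: bool = False) -> xr.DataArray:
    values = tifffile.imread(str(path))
    if as_bool:
        values = values.astype(bool)
    return xr.DataArray(values, dims=("y", "x"))


def save_monthly(da: xr.DataArray, path) -> None:
    """Write a (month, y, x) climatology to NetCDF."""
    da.to_dataset(name=da.name or "climate").to_netcdf(str(path), engine="scipy")


def load_monthly(path, var: str | None = None) -> xr.DataArray:
    with xr.open_dataset(str(path), engine="scipy") as ds:
        name = var or list(ds.data_vars)[0]
        da = ds[name].load()
    return monthly_climatology(da.values, name)


def save_params(params: xr.Dataset, path) -> None:
    """Write an HLZ parameter bundle to NetCDF (frost flag as int8)."""
    out = params.copy()
    out["frost_free"] = out["frost_free"].astype(np.int8)
    out.to_netcdf(str(path), engine="scipy")


def load_params(path) -> xr.Dataset:
    with xr.open_dataset(str(path), engine="scipy") as ds:
        params = ds.load()
    params["frost_free"] = params["frost_free"].astype(bool)
    return params


def load_align_rasters(paths: list) -> list[xr.DataArray]:
    """Load several single-band rasters, requiring one shared grid.

    The first raster defines the reference grid; any later file with a
    different shape is rejected with its path in the message (no silent
    resampling).
    """
    fields = []
    ref_shape = None
    for path in paths:
        field = load_field(path)
        if ref_shape is None:
            ref_shape = field.shape
        elif field.shape != ref_shape:
            raise ValueError(
                f"grid mismatch: {path} has shape {field.shape}, expected {ref_shape}"
            )
        fields.append(field)
    return fields


# ---------------------------------------------------------------------------
# world bundle round trip


def _delta_tag(delta: float) -> str:
    return str(delta).replace(".", "p")


def save_world(bundle: WorldBundle, out_dir) -> None:
    """Write a synthetic world bundle to a directory tree.

    Layout: ``climate/`` NetCDF monthly stacks (baseline and per-GCM
    per-level futures), ``crops/`` production/area TIFFs, ``masks/`` TIFFs,
    ``tables/`` CSVs (true niches, crop table), plus the generating config
    as YAML.
    """
    out = Path(out_dir)
    for sub in ("climate", "crops", "masks", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for var in ("tmin", "tmax", "precip"):
        save_monthly(bundle.baseline[var], out / "climate" / f"baseline_{var}.nc")
    for (gcm, delta), trio in bundle.futures.items():
        for var in ("tmin", "tmax", "precip"):
            save_monthly(
                trio[var],
                out / "climate" / f"future_{gcm}_{_delta_tag(delta)}_{var}.nc",
            )

    for crop in bundle.crops:
        save_field(crop.production, out / "crops" / f"{crop.crop_id}_production.tif")
        save_field(crop.physical_area, out / "crops" / f"{crop.crop_id}_area.tif")

    for name, mask in bundle.region_masks.items():
        save_field(mask, out / "masks" / f"region_{name}.tif")
    for name, mask in bundle.latitude_masks.items():
        save_field(mask, out / "masks" / f"lat_{name}.tif")
    save_field(bundle.elevation, out / "masks" / "elevation.tif")
    save_field(bundle.cropland_mask, out / "masks" / "cropland.tif")

    niches = pd.DataFrame(
        [
            {
                "crop_id": n.crop_id,
                "tbio_low": n.tbio_range[0],
                "tbio_high": n.tbio_range[1],
                "precip_low": n.precip_range[0],
                "precip_high": n.precip_range[1],
                "aridity_max": n.aridity_max,
            }
            for n in bundle.true_niches.values()
        ]
    )
    niches.to_csv(out / "tables" / "true_niches.csv", index=False)
    crops_tab = pd.DataFrame(
        [
            {"crop_id": c.crop_id, "food_flag": int(c.food_flag), "group": c.group}
            for c in bundle.crops
        ]
    )
    crops_tab.to_csv(out / "tables" / "crop_table.csv", index=False)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(bundle.config), fh)


def world_config_from_yaml(path) -> WorldConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "warming_deltas" in raw:
        raw["warming_deltas"] = tuple(raw["warming_deltas"])
    if "precip_scale_factors" in raw:
        raw["precip_scale_factors"] = tuple(raw["precip_scale_factors"])
    return WorldConfig(**raw)


def load_world(world_dir) -> WorldBundle:
    """Regenerate the bundle from a saved world's config.

    The bundle is fully determined by its configuration, so reloading simply
    regenerates it (bit-identical by the determinism guarantee); the on-disk
    rasters serve interchange with other tools.
    """
    cfg = world_config_from_yaml(Path(world_dir) / "config.yaml")
    return generate_world(cfg)


# ---------------------------------------------------------------------------
# provenance


@dataclasses.dataclass
class ProvenanceRecord:
    """What produced a set of outputs: config digest, version, decisions."""

    config_hash: str
    software_version: str
    decisions: dict
    stage_digests: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def for_run(cls, config, decisions: dict) -> "ProvenanceRecord":
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            software_version=__version__,
            decisions=dict(decisions),
        )

    def add_digest(self, stage: str, array) -> None:
        arr = np.ascontiguousarray(np.asarray(array))
        self.stage_digests[stage] = hashlib.sha256(arr.tobytes()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
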