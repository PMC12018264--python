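"""Synthetic world generator with known ground-truth crop niches.

Builds a small, fully self-consistent bundle of everything the analysis
consumes — baseline monthly climate, pseudo-GCM future climatologies at
configurable warming offsets, crops whose production is placed inside known
climatic niches, region/latitude/elevation masks — so every downstream stage
can be tested against exposed ground truth without downloading real data.

The climate is deliberately stylised rather than physical:

* monthly mean temperature = latitudinal gradient (warm equator, cold poles)
  + a seasonal sinusoid whose amplitude grows poleward (opposite phase in
  the two hemispheres) + white noise; tmin/tmax bracket it symmetrically;
* precipitation follows a latitudinal band structure (wet equator, dry
  subtropics, moderate mid-latitudes, dry poles) with longitudinal
  modulation and log-normal noise, so the aridity axis varies meaningfully;
* pseudo-GCMs share each warming level's temperature offset and
  precipitation scale factor and differ only by seeded noise, which makes
  majority-vote behaviour predictable;
* each crop's production is positive only where the baseline Holdridge
  parameters fall inside its :class:`TrueNiche` box, except for a
  configurable *marginal scatter* — a small production share placed on
  cells outside the niche to exercise the lowest-5% marginal rule.

Identical configuration (including seed) reproduces the bundle bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from . import climate as cl
from .scs import CropLayer

__all__ = ["WorldConfig", "TrueNiche", "WorldBundle", "generate_world", "ground_truth_report"]

#: Nominal cell size [ha] from which physical cropland areas are drawn.
CELL_NOMINAL_HA = 8500.0

_CROP_NAMES = [
    "wheat", "rice", "maize", "cassava", "soybean", "barley",
    "sorghum", "potato", "bean", "groundnut",
]
_CROP_GROUPS = {
    "wheat": "cereals", "rice": "cereals", "maize": "cereals",
    "barley": "cereals", "sorghum": "cereals",
    "cassava": "starchy roots", "potato": "starchy roots",
    "soybean": "oil crops", "groundnut": "oil crops",
    "bean": "pulses",
}


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world.

    ``warming_deltas`` [°C] and ``precip_scale_factors`` [-] define the
    pseudo warming levels; they must have equal length with strictly
    increasing deltas.  ``marginal_share`` is the fraction of each crop's
    total production scattered outside its true niche.
    """

    grid_rows: int = 60
    grid_cols: int = 120
    n_crops: int = 6
    n_gcms: int = 4
    warming_deltas: tuple = (1.5, 2.0, 3.0, 4.0)
    precip_scale_factors: tuple = (0.98, 0.96, 0.93, 0.90)
    seed: int = 0
    noise_sd_temp: float = 0.3
    noise_sd_precip_log: float = 0.05
    marginal_share: float = 0.02

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_crops", "n_gcms"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("noise_sd_temp", "noise_sd_precip_log", "marginal_share"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0 <= self.marginal_share < 0.5):
            raise ValueError(f"marginal_share must be in [0, 0.5), got {self.marginal_share!r}")
        deltas = tuple(float(d) for d in self.warming_deltas)
        scales = tuple(float(s) for s in self.precip_scale_factors)
        if any(not math.isfinite(d) for d in deltas):
            raise ValueError("warming_deltas must be finite")
        if any(not math.isfinite(s) or s < 0 for s in scales):
            raise ValueError("precip_scale_factors must be finite and >= 0")
        if len(deltas) != len(scales):
            raise ValueError(
                "warming_deltas and precip_scale_factors must have equal length"
            )
        if len(deltas) > 1 and not all(a < b for a, b in zip(deltas, deltas[1:])):
            raise ValueError("warming_deltas must be strictly increasing")
        object.__setattr__(self, "warming_deltas", deltas)
        object.__setattr__(self, "precip_scale_factors", scales)
        if self.n_crops > len(_CROP_NAMES):
            raise ValueError(f"n_crops must be <= {len(_CROP_NAMES)}")


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth climatic niche box for one synthetic crop."""

    crop_id: str
    tbio_range: tuple  # [low, high] °C
    precip_range: tuple  # [low, high] mm/yr
    aridity_max: float

    def __post_init__(self) -> None:
        if not self.tbio_range[0] < self.tbio_range[1]:
            raise ValueError("tbio_range: low must be < high")
        if not self.precip_range[0] < self.precip_range[1]:
            raise ValueError("precip_range: low must be < high")
        if not self.aridity_max > 0:
            raise ValueError("aridity_max must be > 0")

    def contains(self, params: xr.Dataset) -> xr.DataArray:
        """Boolean field: baseline parameters inside the niche box."""
        bt = params["biotemperature"]
        pr = params["annual_precip"]
        ar = params["aridity"]
        return (
            (bt >= self.tbio_range[0])
            & (bt <= self.tbio_range[1])
            & (pr >= self.precip_range[0])
            & (pr <= self.precip_range[1])
            & (ar <= self.aridity_max)
        )


@dataclass
class WorldBundle:
    """Everything :func:`generate_world` produces, with exposed ground truth."""

    config: WorldConfig
    baseline: dict            # {"tmin","tmax","precip"} monthly DataArrays
    futures: dict             # (gcm, level_delta) -> same trio
    baseline_params: xr.Dataset
    crops: list               # CropLayer per crop
    true_niches: dict         # crop_id -> TrueNiche
    region_masks: dict        # name -> boolean DataArray
    latitude_masks: dict
    elevation: xr.DataArray
    cropland_mask: xr.DataArray = None
    gcm_names: list = dc_field(default_factory=list)


def _latitudes(rows: int) -> np.ndarray:
    half = 90.0 / rows
    return np.linspace(90.0 - half, -90.0 + half, rows)


def _baseline_climate(config: WorldConfig, rng: np.random.Generator) -> dict:
    rows, cols = config.grid_rows, config.grid_cols
    lat = _latitudes(rows)[:, None]  # (rows, 1)
    months = np.arange(12)[:, None, None]

    annual_mean = 28.0 - 43.0 * (np.abs(lat) / 90.0) ** 1.6
    season_amp = 1.0 + 14.0 * np.abs(lat) / 90.0
    hemisphere = np.where(lat >= 0, 1.0, -1.0)
    seasonal = season_amp * hemisphere * np.cos(2 * np.pi * (months - 6) / 12.0)
    tmean = annual_mean[None, :, :] + seasonal
    tmean = np.broadcast_to(tmean, (12, rows, cols)).copy()
    tmean += rng.normal(0.0, config.noise_sd_temp, size=tmean.shape)

    spread = 5.0  # tmin/tmax bracket the mean symmetrically
    tmin = tmean - spread
    tmax = tmean + spread

    lat_pts = np.array([0, 15, 25, 40, 55, 75, 90], dtype=float)
    annual_precip = np.interp(
        np.abs(lat[:, 0]), lat_pts, [2200, 1500, 350, 700, 900, 450, 250]
    )[:, None]
    lon_factor = np.exp(0.4 * np.sin(2 * np.pi * np.arange(cols) / cols))[None, :]
    monthly = np.broadcast_to(
        (annual_precip * lon_factor / 12.0)[None, :, :], (12, rows, cols)
    ).copy()
    monthly *= np.exp(
        rng.normal(0.0, config.noise_sd_precip_log, size=monthly.shape)
    )

    return {
        "tmin": cl.monthly_climatology(tmin, "tmin"),
        "tmax": cl.monthly_climatology(tmax, "tmax"),
        "precip": cl.monthly_climatology(monthly, "precip"),
    }


def _future_climate(
    baseline: dict, delta: float, scale: float, config: WorldConfig,
    rng: np.random.Generator,
) -> dict:
    shape = baseline["tmin"].shape
    t_noise = rng.normal(0.0, config.noise_sd_temp, size=shape)
    p_noise = np.exp(rng.normal(0.0, config.noise_sd_precip_log, size=shape))
    return {
        "tmin": (baseline["tmin"] + delta + t_noise).rename("tmin"),
        "tmax": (baseline["tmax"] + delta + t_noise).rename("tmax"),
        "precip": (baseline["precip"] * scale * p_noise).rename("precip"),
    }


def _draw_niche(
    crop_id: str, params: xr.Dataset, rng: np.random.Generator
) -> TrueNiche:
    """Quantile-anchored niche box guaranteed to be occupied by some cells."""
    bt = params["biotemperature"].values.ravel()
    centre = rng.uniform(0.2, 0.8)
    width = rng.uniform(0.15, 0.3)
    lo_q, hi_q = max(0.02, centre - width / 2), min(0.98, centre + width / 2)
    bt_lo, bt_hi = np.quantile(bt, [lo_q, hi_q])
    if bt_hi - bt_lo < 0.5:
        bt_hi = bt_lo + 0.5
    in_bt = (bt >= bt_lo) & (bt <= bt_hi)
    pr = params["annual_precip"].values.ravel()[in_bt]
    pr_lo, pr_hi = np.quantile(pr, [0.05, 0.95])
    if pr_hi <= pr_lo:
        pr_hi = pr_lo + 1.0
    ar = params["aridity"].values.ravel()[in_bt]
    ar_max = float(np.quantile(ar, 0.9))
    if ar_max <= 0:
        ar_max = 1.0
    return TrueNiche(crop_id, (float(bt_lo), float(bt_hi)), (float(pr_lo), float(pr_hi)), ar_max)


def _crop_production(
    niche: TrueNiche,
    params: xr.Dataset,
    config: WorldConfig,
    rng: np.random.Generator,
) -> tuple[xr.DataArray, xr.DataArray]:
    template = params["annual_precip"]
    inside = niche.contains(params).values
    prod = np.zeros(inside.shape)
    prod[inside] = rng.lognormal(mean=3.0, sigma=1.0, size=int(inside.sum()))

    total_inside = prod.sum()
    if config.marginal_share > 0 and total_inside > 0:
        outside_idx = np.flatnonzero(~inside.ravel())
        if outside_idx.size:
            n_marg = max(1, int(0.02 * prod.size))
            n_marg = min(n_marg, outside_idx.size)
            chosen = rng.choice(outside_idx, size=n_marg, replace=False)
            total_marginal = (
                config.marginal_share / (1 - config.marginal_share) * total_inside
            )
            weights = rng.uniform(0.5, 1.5, size=n_marg)
            flat = prod.ravel()
            flat[chosen] = total_marginal * weights / weights.sum()
            prod = flat.reshape(prod.shape)

    area = np.zeros(prod.shape)
    has_prod = prod > 0
    area[has_prod] = rng.uniform(0.0, 1.0, size=int(has_prod.sum())) * CELL_NOMINAL_HA
    area[has_prod] = np.maximum(area[has_prod], 1.0)  # (0, nominal] — never 0

    production = xr.DataArray(prod, dims=template.dims, coords=template.coords)
    physical = xr.DataArray(area, dims=template.dims, coords=template.coords)
    return production, physical


def _masks(config: WorldConfig, elevation: xr.DataArray) -> tuple[dict, dict]:
    rows, cols = config.grid_rows, config.grid_cols
    template = elevation
    half_r, half_c = rows // 2, cols // 2
    grid = np.zeros((rows, cols), dtype=int)
    grid[:half_r, half_c:] = 1
    grid[half_r:, :half_c] = 2
    grid[half_r:, half_c:] = 3
    names = ["northwest", "northeast", "southwest", "southeast"]
    regions = {
        name: xr.DataArray(grid == i, dims=template.dims, coords=template.coords)
        for i, name in enumerate(names)
    }
    lat = np.broadcast_to(_latitudes(rows)[:, None], (rows, cols))
    bands = {
        "tropical": np.abs(lat) < 23.5,
        "temperate": (np.abs(lat) >= 23.5) & (np.abs(lat) < 55.0),
        "boreal_polar": np.abs(lat) >= 55.0,
    }
    latitude = {
        name: xr.DataArray(m, dims=template.dims, coords=template.coords)
        for name, m in bands.items()
    }
    return regions, latitude


def _elevation_field(config: WorldConfig, rng: np.random.Generator) -> xr.DataArray:
    rows, cols = config.grid_rows, config.grid_cols
    yy, xx = np.mgrid[0:rows, 0:cols]
    elev = np.zeros((rows, cols))
    for _ in range(6):  # a few smooth mountain massifs
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        height = rng.uniform(500, 4000)
        width = rng.uniform(3, max(4, rows / 4))
        elev += height * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2)))
    return xr.DataArray(elev, dims=("y", "x"), name="elevation")


def generate_world(config: WorldConfig) -> WorldBundle:
    """Generate the full synthetic bundle (deterministic for a given config)."""
    rng = np.random.default_rng(config.seed)

    baseline = _baseline_climate(config, rng)
    baseline_params = cl.compute_hlz_params(
        baseline["tmin"], baseline["tmax"], baseline["precip"]
    )

    gcm_names = [f"pseudo-gcm-{i + 1}" for i in range(config.n_gcms)]
    futures = {}
    for gcm in gcm_names:
        for delta, scale in zip(config.warming_deltas, config.precip_scale_factors):
            futures[(gcm, delta)] = _future_climate(
                baseline, delta, scale, config, rng
            )

    crops = []
    true_niches = {}
    for i in range(config.n_crops):
        crop_id = _CROP_NAMES[i]
        niche = _draw_niche(crop_id, baseline_params, rng)
        production, physical = _crop_production(niche, baseline_params, config, rng)
        crops.append(
            CropLayer(
                crop_id,
                production,
                physical,
                food_flag=True,
                group=_CROP_GROUPS[crop_id],
            )
        )
        true_niches[crop_id] = niche

    elevation = _elevation_field(config, rng)
    regions, latitude = _masks(config, elevation)

    cropland = None
    for crop in crops:
        has = (crop.production > 0) | (crop.physical_area > 0)
        cropland = has if cropland is None else (cropland | has)

    return WorldBundle(
        config=config,
        baseline=baseline,
        futures=futures,
        baseline_params=baseline_params,
        crops=crops,
        true_niches=true_niches,
        region_masks=regions,
        latitude_masks=latitude,
        elevation=elevation,
        cropland_mask=cropland.rename("cropland"),
        gcm_names=gcm_names,
    )


def ground_truth_report(bundle: WorldBundle) -> pd.DataFrame:
    """Expected direction of niche-area change per crop and warming level.

    For each crop and each warming delta, recomputes biotemperature under a
    uniform temperature shift and flags whether cells currently inside the
    crop's biotemperature range would leave it (expected loss — e.g.
    equator-side cells pushed above the upper bound) and whether cells
    currently outside would enter it (expected gain — e.g. pole-side cells
    warming into range).  A zero delta reports direction "none".
    """
    rows = []
    tmean = cl.monthly_mean_estimate(bundle.baseline["tmin"], bundle.baseline["tmax"])
    bt0 = cl.biotemperature(tmean).values
    for delta in bundle.config.warming_deltas:
        bt1 = cl.biotemperature(tmean + delta).values
        for crop_id, niche in bundle.true_niches.items():
            lo, hi = niche.tbio_range
            in0 = (bt0 >= lo) & (bt0 <= hi)
            in1 = (bt1 >= lo) & (bt1 <= hi)
            if delta == 0:
                loss = gain = False
            else:
                loss = bool((in0 & ~in1).any())
                gain = bool((~in0 & in1).any())
            if not loss and not gain:
                direction = "none"
            elif loss and gain:
                direction = "mixed"
            else:
                direction = "loss" if loss else "gain"
            rows.append(
                {
                    "crop_id": crop_id,
                    "delta": delta,
                    "tbio_low": lo,
                    "tbio_high": hi,
                    "expected_loss": loss,
                    "expected_gain": gain,
                    "expected_direction": direction,
                }
            )
    return pd.DataFrame(rows)
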