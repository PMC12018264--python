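"""End-to-end orchestration of the Safe Climatic Space analysis.

Stage order, mirroring how the method runs on real data:

1. Holdridge parameters for the baseline climatology and, per GCM and
   warming level, for the future climatologies (period pairs are first
   interpolated to the level's crossing year when given).
2. Per-crop niche delineation from baseline climate and major-production
   cells.
3. Membership cubes per crop x GCM x level, on two extents: the crop's own
   production area (risk indicators) and the total cropland of all crops
   (area change and diversity), plus majority-vote consensus fields.
4. Risk indicators: lowest risky warming level per cell (+ regional
   cropland-area shares) and ensemble spread of production outside the
   niche per crop and group.
5. Cropland-area change within each niche (net / gain / loss ratios,
   per crop and group).
6. Potential crop diversity, its change categories and zonal summaries over
   regions, latitude bands and elevation bands.

Re-running with the same inputs and settings is bit-identical; a
:class:`~cropscs.io.ProvenanceRecord` documents the decisions in force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import area_diversity as ad
from . import climate as cl
from . import risk as rk
from .io import ProvenanceRecord
from .projection import ensemble_membership, majority_vote
from .scs import CropLayer, SCSDefinition, default_binning, delineate_scs, scs_membership
from .synthetic import WorldBundle

__all__ = ["PipelineSettings", "PipelineResult", "run_pipeline", "params_at_level"]


@dataclass(frozen=True)
class PipelineSettings:
    """Analysis thresholds and discretisation settings."""

    major_share: float = 0.95
    marginal_share: float = 0.05
    risk_thresholds: tuple = (0.25, 0.50, 0.75)
    bins_per_class: int = 2
    elevation_edges: tuple = ad.DEFAULT_ELEVATION_EDGES

    def __post_init__(self) -> None:
        for name in ("major_share", "marginal_share"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        for t in self.risk_thresholds:
            if not (0 < t <= 1):
                raise ValueError("risk thresholds must be in (0, 1]")


@dataclass
class PipelineResult:
    """All stage outputs of one run, keyed the way the stages produce them."""

    scs: dict                      # crop_id -> SCSDefinition
    baseline_membership: dict      # crop_id -> bool field (full grid)
    membership: dict               # (crop_id, level) -> bool (gcm, y, x) cube
    consensus: dict                # (crop_id, level) -> bool field
    risk_maps: dict                # threshold -> risk-level field
    risk_regional: pd.DataFrame
    production_outside: pd.DataFrame   # crop x level ensemble spread
    group_outside: pd.DataFrame        # group x level aggregated shares
    area_per_crop: pd.DataFrame        # crop x level x gcm area bookkeeping
    area_net: pd.DataFrame             # crop x level net% ensemble spread
    group_area: pd.DataFrame           # group x level gain/loss/net spread
    diversity_counts: dict             # level (or "baseline") -> count field
    diversity_categories: dict         # level -> category field
    diversity_zonal: pd.DataFrame
    provenance: ProvenanceRecord
    levels: list = field(default_factory=list)


def params_at_level(
    y0_params: xr.Dataset, y1_params: xr.Dataset, spec: cl.WarmingLevelSpec
) -> xr.Dataset:
    """Interpolate two period parameter bundles to a warming-level year.

    All parameters, including the binary frost indicator, are interpolated
    linearly; the frost field is then re-binarised at 0.5.
    """
    out = cl.interpolate_warming_level(
        y0_params.astype(float), y1_params.astype(float), spec
    )
    out["frost_free"] = cl.threshold_frost(out["frost_free"])
    return out


def _future_params(world: WorldBundle) -> dict:
    """(gcm, level) -> HLZ parameter bundle for every pseudo-GCM future."""
    out = {}
    for (gcm, delta), trio in world.futures.items():
        out[(gcm, delta)] = cl.compute_hlz_params(
            trio["tmin"], trio["tmax"], trio["precip"]
        )
    return out


def _elevation_masks(elevation: xr.DataArray, edges: tuple) -> dict:
    masks = {}
    lo = -np.inf
    labels = []
    for edge in list(edges) + [np.inf]:
        if np.isinf(edge):
            labels.append(f">{edges[-1]:.0f}m")
        elif np.isinf(lo):
            labels.append(f"<{edge:.0f}m")
        else:
            labels.append(f"{lo:.0f}-{edge:.0f}m")
        masks[labels[-1]] = (elevation > lo) & (elevation <= edge)
        lo = edge
    # reopen the first band at the bottom so the bands partition everything
    first = labels[0]
    masks[first] = elevation <= edges[0]
    return masks


def run_pipeline(
    world: WorldBundle, settings: PipelineSettings | None = None
) -> PipelineResult:
    """Run the full analysis on a (synthetic or loaded) world bundle."""
    if settings is None:
        settings = PipelineSettings()
    binning = default_binning(settings.bins_per_class)
    levels = list(world.config.warming_deltas)
    crops: list[CropLayer] = world.crops
    baseline_params = world.baseline_params
    future_params = _future_params(world)
    cropland = world.cropland_mask
    cropland_area = sum(c.physical_area for c in crops).rename("cropland_area")

    provenance = ProvenanceRecord.for_run(
        world.config,
        {
            "major_share": settings.major_share,
            "marginal_share": settings.marginal_share,
            "risk_thresholds": list(settings.risk_thresholds),
            "bins_per_class": settings.bins_per_class,
            "vote_rule": "within iff >= ceil(n_gcms/2) members within",
            "percentile_method": "linear interpolation between order statistics",
            "aridity_cap": float(cl.ARIDITY_CAP),
        },
    )

    # --- stage 2: niche delineation -------------------------------------
    scs: dict[str, SCSDefinition] = {}
    baseline_membership: dict[str, xr.DataArray] = {}
    for crop in crops:
        scs[crop.crop_id] = delineate_scs(
            crop, baseline_params, binning, settings.major_share
        )
        baseline_membership[crop.crop_id] = scs_membership(
            baseline_params, scs[crop.crop_id]
        )

    # --- stage 3: membership cubes and consensus ------------------------
    membership: dict[tuple, xr.DataArray] = {}
    consensus: dict[tuple, xr.DataArray] = {}
    for crop in crops:
        for level in levels:
            gcm_params = {
                gcm: future_params[(gcm, level)] for gcm in world.gcm_names
            }
            cube = ensemble_membership(scs[crop.crop_id], gcm_params)
            membership[(crop.crop_id, level)] = cube
            consensus[(crop.crop_id, level)] = majority_vote(cube)

    # --- stage 4: risk indicators ---------------------------------------
    shares_by_level = {
        level: rk.cell_share_outside(
            crops, {c.crop_id: consensus[(c.crop_id, level)] for c in crops}
        )
        for level in levels
    }
    risk_maps = {
        thr: rk.lowest_risk_level(shares_by_level, thr)
        for thr in settings.risk_thresholds
    }
    risk_regional = rk.regional_risk_area_share(
        risk_maps[settings.risk_thresholds[0]],
        world.region_masks,
        cropland_area,
        levels,
    )

    outside_rows = []
    per_crop_by_level: dict[float, dict] = {level: {} for level in levels}
    for crop in crops:
        extent = crop.production > 0
        for level in levels:
            cube = membership[(crop.crop_id, level)] & extent
            stats = rk.production_outside_by_crop(crop, cube)
            per_crop_by_level[level][crop.crop_id] = stats
            outside_rows.append(
                {"crop_id": crop.crop_id, "level": level, **stats}
            )
    production_outside = pd.DataFrame(outside_rows)
    groups = {c.crop_id: c.group for c in crops}
    group_outside = pd.concat(
        [
            rk.aggregate_group_shares(per_crop_by_level[level], groups).assign(
                level=level
            )
            for level in levels
        ],
        ignore_index=True,
    )

    # --- stage 5: cropland area within the niche ------------------------
    area_rows = []
    per_crop_per_gcm_by_level: dict[float, dict] = {level: {} for level in levels}
    for crop in crops:
        base_member = baseline_membership[crop.crop_id] & cropland
        for level in levels:
            per_gcm = {}
            for gcm in world.gcm_names:
                member = membership[(crop.crop_id, level)].sel(gcm=gcm, drop=True)
                change = ad.area_change(
                    base_member, member & cropland, cropland_area
                )
                per_gcm[gcm] = change
                area_rows.append(
                    {
                        "crop_id": crop.crop_id,
                        "level": level,
                        "gcm": gcm,
                        "a_baseline_ha": change.a_baseline,
                        "a_warming_ha": change.a_warming,
                        "a_gain_ha": change.a_gain,
                        "a_loss_ha": change.a_loss,
                        "net_pct": ad.net_change_pct(
                            change.a_warming, change.a_baseline
                        ),
                    }
                )
            per_crop_per_gcm_by_level[level][crop.crop_id] = per_gcm
    area_per_crop = pd.DataFrame(area_rows)
    net_stats = (
        area_per_crop.groupby(["crop_id", "level"])["net_pct"]
        .agg(
            net_median="median",
            net_p25=lambda s: float(np.percentile(s, 25)),
            net_p75=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    area_net = net_stats
    group_area = pd.concat(
        [
            ad.group_area_stats(per_crop_per_gcm_by_level[level], groups).assign(
                level=level
            )
            for level in levels
        ],
        ignore_index=True,
    )

    # --- stage 6: potential crop diversity ------------------------------
    food_crops = [c.crop_id for c in crops if c.food_flag]
    base_members_cropland = {
        c: (baseline_membership[c] & cropland) for c in food_crops
    }
    diversity_counts = {"baseline": ad.potential_diversity(base_members_cropland)}
    diversity_categories = {}
    zonal_frames = []
    zone_sets = {
        "region": world.region_masks,
        "latitude": world.latitude_masks,
        "elevation": _elevation_masks(world.elevation, settings.elevation_edges),
    }
    for level in levels:
        level_members = {
            c: (consensus[(c, level)] & cropland) for c in food_crops
        }
        counts = ad.potential_diversity(level_members)
        diversity_counts[level] = counts
        cats = ad.classify_diversity_change(diversity_counts["baseline"], counts)
        diversity_categories[level] = cats
        for zone_kind, masks in zone_sets.items():
            frame = ad.zonal_category_summary(
                cats, {k: m & cropland for k, m in masks.items()}, cropland_area
            )
            frame["zone_kind"] = zone_kind
            frame["level"] = level
            zonal_frames.append(frame)
    diversity_zonal = pd.concat(zonal_frames, ignore_index=True)

    provenance.add_digest("cropland_area", cropland_area.values)
    for thr, rmap in risk_maps.items():
        provenance.add_digest(f"risk_map_{thr}", np.nan_to_num(rmap.values, posinf=9e9))

    return PipelineResult(
        scs=scs,
        baseline_membership=baseline_membership,
        membership=membership,
        consensus=consensus,
        risk_maps=risk_maps,
        risk_regional=risk_regional,
        production_outside=production_outside,
        group_outside=group_outside,
        area_per_crop=area_per_crop,
        area_net=area_net,
        group_area=group_area,
        diversity_counts=diversity_counts,
        diversity_categories=diversity_categories,
        diversity_zonal=diversity_zonal,
        provenance=provenance,
        levels=levels,
    )
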