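"""Climate-risk indicators for current crop production.

Two indicators quantify how global warming threatens production where it
happens today:

1. **Lowest risky warming level** (cell level, consensus climate): per grid
   cell, the production-weighted share of current output of all food crops
   that falls outside its crop's niche is computed at each warming level
   (using the majority-vote consensus membership per crop), and the cell is
   labelled with the lowest level at which that share reaches a threshold
   (25% by default; 50% and 75% as sensitivity settings).  Cells never
   reaching the threshold get the sentinel ``NEVER_AT_RISK``.  Results are
   summarised per region as the share of cropland hectares at risk.

2. **Production outside the niche** (crop level, full ensemble spread): per
   crop and warming level, each GCM's estimate of the production volume in
   cells outside the niche is divided by the crop's reference production;
   the ensemble is summarised as median and interquartile percentiles, and
   aggregated over crop groups by summing tonnages before normalising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .climate import _check_aligned
from .projection import ensemble_quantiles
from .scs import CropLayer

__all__ = [
    "NEVER_AT_RISK",
    "cell_share_outside",
    "lowest_risk_level",
    "regional_risk_area_share",
    "production_outside_by_crop",
    "aggregate_group_shares",
]

#: Sentinel risk-map value for cells never pushed over the threshold at any
#: studied warming level.
NEVER_AT_RISK = np.inf


def cell_share_outside(
    crops: list[CropLayer], consensus: dict[str, xr.DataArray]
) -> xr.DataArray:
    """Per-cell share of total food-crop production outside its crop's niche.

    ``consensus`` maps crop_id -> consensus (majority-vote) membership field
    at one warming level.  Cells with zero total production are NaN-masked.
    """
    if not crops:
        raise ValueError("no crops supplied")
    total = None
    outside = None
    for crop in crops:
        member = consensus[crop.crop_id]
        _check_aligned(crop.production, member)
        prod = crop.production
        out = prod.where(~member, 0.0)
        total = prod if total is None else total + prod
        outside = out if outside is None else outside + out
    share = (outside / total.where(total > 0)).rename("share_outside")
    return share


def lowest_risk_level(
    shares_by_level: dict[float, xr.DataArray], threshold: float = 0.25
) -> xr.DataArray:
    """Lowest warming level at which the outside-share reaches the threshold.

    Levels are scanned in ascending order and the first crossing wins (a
    later drop back below the threshold does not rescind the label).  Cells
    never crossing get ``NEVER_AT_RISK``; cells with no production are NaN.
    """
    if not shares_by_level:
        raise ValueError("no warming levels supplied")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    levels = sorted(shares_by_level)
    ref = shares_by_level[levels[0]]
    risk = xr.full_like(ref, NEVER_AT_RISK, dtype=float)
    for level in reversed(levels):
        share = shares_by_level[level]
        _check_aligned(ref, share)
        risk = xr.where(share >= threshold, float(level), risk)
    risk = risk.where(ref.notnull())
    return risk.rename("lowest_risk_level")


def regional_risk_area_share(
    risk: xr.DataArray,
    region_masks: dict[str, xr.DataArray],
    cropland_area: xr.DataArray,
    levels: list[float],
) -> pd.DataFrame:
    """Share of each region's cropland hectares at risk by each level.

    A cell counts toward level L if its risk label is <= L, so shares are
    cumulative (non-decreasing in L).  Region masks must not overlap.
    Cropland cells carrying area but no food-crop production (risk NaN)
    stay in the denominator.
    """
    _check_aligned(risk, cropland_area)
    overlap = None
    for mask in region_masks.values():
        _check_aligned(risk, mask)
        overlap = mask if overlap is None else overlap.astype(int) + mask.astype(int)
    if overlap is not None and bool((overlap > 1).any()):
        raise ValueError("overlapping region masks")
    rows = []
    area = cropland_area.values
    riskv = risk.values
    for region, mask in region_masks.items():
        m = mask.values.astype(bool)
        denom = float(area[m].sum())
        for level in levels:
            at_risk = m & np.isfinite(riskv) & (riskv <= level)
            num = float(area[at_risk].sum())
            rows.append(
                {
                    "region": region,
                    "level": level,
                    "area_share_at_risk": num / denom if denom > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def production_outside_by_crop(
    crop: CropLayer,
    gcm_membership: xr.DataArray,
    region_mask: xr.DataArray | None = None,
) -> dict[str, float]:
    """Ensemble spread of the crop's production share outside its niche.

    ``gcm_membership`` is the boolean per-GCM membership cube (dims
    ``gcm, y, x``) on the crop's production extent at one warming level.
    Returns median/p25/p75 of the outside share plus the same statistics in
    tons ("median_t" etc.) and the reference total, optionally restricted to
    a region before normalisation.
    """
    prod = crop.production
    if region_mask is not None:
        _check_aligned(prod, region_mask)
        prod = prod.where(region_mask, 0.0)
    _check_aligned(prod, gcm_membership.isel(gcm=0, drop=True))
    reference = float(prod.sum())
    if reference <= 0:
        raise ValueError(f"{crop.crop_id}: zero reference production")
    outside_t = []
    for g in range(gcm_membership.sizes["gcm"]):
        member = gcm_membership.isel(gcm=g, drop=True)
        outside_t.append(float(prod.where(~member, 0.0).sum()))
    q_t = ensemble_quantiles(outside_t)
    result = {k: v / reference for k, v in q_t.items()}
    result.update({f"{k}_t": v for k, v in q_t.items()})
    result["reference_t"] = reference
    return result


def aggregate_group_shares(
    per_crop: dict[str, dict[str, float]], groups: dict[str, str]
) -> pd.DataFrame:
    """Aggregate per-crop outside-production statistics into crop groups.

    Per group (and for all crops in total, row "all"), each statistic is the
    sum of the member crops' tonnages outside the niche divided by the sum
    of their reference tonnages.
    """
    for crop_id in per_crop:
        if crop_id not in groups:
            raise ValueError(f"crop {crop_id!r} has no group assignment")
    rows = []
    group_names = sorted(set(groups[c] for c in per_crop))
    for group in group_names + ["all"]:
        members = [
            c for c in per_crop if group == "all" or groups[c] == group
        ]
        ref = sum(per_crop[c]["reference_t"] for c in members)
        row = {"group": group, "reference_t": ref}
        for stat in ("median", "p25", "p75"):
            row[stat] = sum(per_crop[c][f"{stat}_t"] for c in members) / ref
        rows.append(row)
    return pd.DataFrame(rows)
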