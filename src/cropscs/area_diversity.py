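"""Cropland area within the niche and potential crop diversity.

Beyond each crop's current production area, the analysis asks how much of
the *total* cropland (of all crops) has a climate inside a crop's niche, and
how that changes with warming:

* net change,  (A_warming - A_baseline) / A_baseline x 100%;
* gain and loss ratios,  A_change / A_baseline x 100%, where A_change is the
  cropland area shifting into (gain) or out of (loss) the niche — by
  construction net% = gain% - loss%.

Areas are always physical cropland hectares supplied with the data, never
geometric cell areas.

**Potential crop diversity** of a cell is the number of food crops whose
niche contains the cell's climate, irrespective of where those crops grow
today.  Its change from baseline is expressed as a percentage and binned
into the category system used for mapping: exactly -100%, then 25-point
bins ((-100,-75], ..., (+75,+100]), "no change" for exactly 0, and for cells
hosting no crop's niche at baseline ("marginal in baseline") either
"cropland with emerging climatic potential" (enters at least one niche
under warming) or "marginal in baseline and outside SCS under warming
level".  Category shares are summarised over regions, latitude bands and
elevation bands as shares of zonal cropland hectares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .climate import _check_aligned

__all__ = [
    "AreaChange",
    "cropland_area_within_scs",
    "net_change_pct",
    "gain_loss_ratios",
    "area_change",
    "group_area_stats",
    "potential_diversity",
    "classify_diversity_change",
    "zonal_category_summary",
    "group_diversity",
    "DIVERSITY_CATEGORIES",
    "DEFAULT_ELEVATION_EDGES",
]

#: Elevation-band edges [m]; the >2500 m band is reported separately because
#: high-altitude cropland is where emerging climatic potential concentrates.
DEFAULT_ELEVATION_EDGES = (500.0, 1500.0, 2500.0)

#: Integer-coded diversity-change categories (sidecar legend for rasters).
DIVERSITY_CATEGORIES = {
    0: "no change",
    -1: "loss -100%",
    -2: "loss (-100,-75]%",
    -3: "loss (-75,-50]%",
    -4: "loss (-50,-25]%",
    -5: "loss (-25,0)%",
    1: "gain (0,25]%",
    2: "gain (25,50]%",
    3: "gain (50,75]%",
    4: "gain (75,100]%",
    5: "gain >100%",
    10: "cropland with emerging climatic potential",
    11: "marginal in baseline and outside SCS under warming level",
}


class AreaChange:
    """Cropland-area bookkeeping for one crop at one warming level [ha].

    Satisfies A_warming = A_baseline + A_gain - A_loss by construction.
    """

    def __init__(self, a_baseline: float, a_warming: float, a_gain: float, a_loss: float):
        for name, v in [
            ("a_baseline", a_baseline),
            ("a_warming", a_warming),
            ("a_gain", a_gain),
            ("a_loss", a_loss),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        self.a_baseline = a_baseline
        self.a_warming = a_warming
        self.a_gain = a_gain
        self.a_loss = a_loss

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AreaChange(baseline={self.a_baseline:.1f} ha, "
            f"warming={self.a_warming:.1f} ha, gain={self.a_gain:.1f}, "
            f"loss={self.a_loss:.1f})"
        )


def cropland_area_within_scs(
    membership: xr.DataArray, cropland_area: xr.DataArray
) -> float:
    """Total physical cropland hectares in cells within the niche."""
    _check_aligned(membership, cropland_area)
    return float(cropland_area.where(membership, 0.0).sum())


def net_change_pct(a_warming: float, a_baseline: float) -> float:
    """Percentage net change in within-niche cropland area from baseline."""
    if a_baseline <= 0:
        return np.nan
    return (a_warming - a_baseline) / a_baseline * 100.0


def gain_loss_ratios(
    membership_baseline: xr.DataArray,
    membership_level: xr.DataArray,
    cropland_area: xr.DataArray,
) -> dict[str, float]:
    """Gain and loss of within-niche cropland area as % of the baseline area.

    gain% counts cropland shifting into the niche, loss% cropland shifting
    out; gain% - loss% equals the net change percentage exactly.
    """
    _check_aligned(membership_baseline, membership_level, cropland_area)
    a_baseline = cropland_area.where(membership_baseline, 0.0).sum()
    gained = cropland_area.where(membership_level & ~membership_baseline, 0.0).sum()
    lost = cropland_area.where(membership_baseline & ~membership_level, 0.0).sum()
    a_baseline, gained, lost = float(a_baseline), float(gained), float(lost)
    if a_baseline <= 0:
        return {"gain_pct": np.nan, "loss_pct": np.nan}
    return {
        "gain_pct": gained / a_baseline * 100.0,
        "loss_pct": lost / a_baseline * 100.0,
    }


def area_change(
    membership_baseline: xr.DataArray,
    membership_level: xr.DataArray,
    cropland_area: xr.DataArray,
) -> AreaChange:
    """Full area bookkeeping (baseline, warming, gain, loss) in hectares."""
    _check_aligned(membership_baseline, membership_level, cropland_area)
    a_base = cropland_area.where(membership_baseline, 0.0).sum()
    a_warm = cropland_area.where(membership_level, 0.0).sum()
    gained = cropland_area.where(membership_level & ~membership_baseline, 0.0).sum()
    lost = cropland_area.where(membership_baseline & ~membership_level, 0.0).sum()
    return AreaChange(float(a_base), float(a_warm), float(gained), float(lost))


def group_area_stats(
    per_crop_per_gcm: dict[str, dict[str, AreaChange]],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Ensemble statistics of group-level area-change ratios.

    Per GCM, the area components of all crops in a group are summed before
    converting to ratios (so large-area crops weigh more); the ensemble of
    per-GCM ratios is then summarised as median/p25/p75 for gain%, loss% and
    net%.
    """
    for crop_id in per_crop_per_gcm:
        if crop_id not in groups:
            raise ValueError(f"crop {crop_id!r} has no group assignment")
    gcms = sorted({g for d in per_crop_per_gcm.values() for g in d})
    rows = []
    group_names = sorted(set(groups[c] for c in per_crop_per_gcm))
    for group in group_names + ["all"]:
        members = [
            c for c in per_crop_per_gcm if group == "all" or groups[c] == group
        ]
        per_gcm = {"gain_pct": [], "loss_pct": [], "net_pct": []}
        for g in gcms:
            base = sum(per_crop_per_gcm[c][g].a_baseline for c in members)
            gain = sum(per_crop_per_gcm[c][g].a_gain for c in members)
            loss = sum(per_crop_per_gcm[c][g].a_loss for c in members)
            warm = sum(per_crop_per_gcm[c][g].a_warming for c in members)
            if base <= 0:
                continue
            per_gcm["gain_pct"].append(gain / base * 100.0)
            per_gcm["loss_pct"].append(loss / base * 100.0)
            per_gcm["net_pct"].append((warm - base) / base * 100.0)
        row = {"group": group}
        for stat, vals in per_gcm.items():
            p25, med, p75 = (
                np.percentile(vals, [25, 50, 75]) if vals else (np.nan,) * 3
            )
            row[f"{stat}_median"] = float(med)
            row[f"{stat}_p25"] = float(p25)
            row[f"{stat}_p75"] = float(p75)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# potential crop diversity


def potential_diversity(memberships: dict[str, xr.DataArray]) -> xr.DataArray:
    """Number of crops whose niche contains each cell's climate."""
    if not memberships:
        raise ValueError("no crop memberships supplied")
    count = None
    ref = None
    for member in memberships.values():
        if ref is None:
            ref = member
        else:
            _check_aligned(ref, member)
        count = member.astype(int) if count is None else count + member.astype(int)
    return count.rename("potential_diversity")


def _pct_category(pct: float) -> int:
    if pct == 0:
        return 0
    if pct == -100:
        return -1
    if pct < 0:
        # left-open/right-closed 25-point bins: (-25,0) -> -5 ... (-100,-75] -> -2
        idx = min(int(np.floor(-pct / 25.0 + 1e-12)), 3)
        return idx - 5
    return min(int(np.ceil(pct / 25.0 - 1e-12)), 5)


def classify_diversity_change(
    base_count: xr.DataArray, level_count: xr.DataArray
) -> xr.DataArray:
    """Integer-coded diversity-change category per cell (see legend).

    Where the baseline count is positive, the percentage change
    (level - base)/base x 100 is binned with -100% and 0 pulled out as their
    own categories.  Where the baseline count is zero the cell is "marginal
    in baseline": it becomes "emerging climatic potential" if at least one
    niche arrives under warming, otherwise the marginal-and-outside category.
    """
    _check_aligned(base_count, level_count)
    base = base_count.values
    lev = level_count.values
    if (base < 0).any() or (lev < 0).any():
        raise ValueError("negative diversity counts")
    cat = np.empty(base.shape, dtype=np.int16)
    pos = base > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (lev - base) / np.where(pos, base, 1) * 100.0
    it = np.nditer(base, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        if base[idx] > 0:
            cat[idx] = _pct_category(float(pct[idx]))
        else:
            cat[idx] = 10 if lev[idx] >= 1 else 11
    return xr.DataArray(
        cat, dims=base_count.dims, coords=base_count.coords, name="diversity_category"
    )


def zonal_category_summary(
    categories: xr.DataArray,
    zone_masks: dict[str, xr.DataArray],
    cropland_area: xr.DataArray,
) -> pd.DataFrame:
    """Cropland-hectare share of each category within each zone.

    Zones (regions, latitude bands or elevation bands) must not overlap;
    shares within a zone sum to 1 over the categories present.
    """
    _check_aligned(categories, cropland_area)
    overlap = None
    for mask in zone_masks.values():
        _check_aligned(categories, mask)
        overlap = mask.astype(int) if overlap is None else overlap + mask.astype(int)
    if overlap is not None and bool((overlap > 1).any()):
        raise ValueError("overlapping zone masks")
    rows = []
    cat = categories.values
    area = cropland_area.values
    for zone, mask in zone_masks.items():
        m = mask.values.astype(bool)
        denom = float(area[m].sum())
        for code in sorted(DIVERSITY_CATEGORIES):
            sel = m & (cat == code)
            ha = float(area[sel].sum())
            if ha == 0 and denom > 0:
                continue
            rows.append(
                {
                    "zone": zone,
                    "category": code,
                    "category_label": DIVERSITY_CATEGORIES[code],
                    "area_ha": ha,
                    "area_share": ha / denom if denom > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def group_diversity(
    memberships: dict[str, xr.DataArray],
    group_crops: list[str],
) -> xr.DataArray:
    """Potential diversity restricted to the crops of one group."""
    if not group_crops:
        raise ValueError("empty crop group")
    subset = {c: memberships[c] for c in group_crops}
    return potential_diversity(subset)
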