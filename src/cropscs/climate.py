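"""Holdridge life-zone climate parameters from monthly climatologies.

The Safe Climatic Space analysis characterises every grid cell's climate by
four annual quantities derived from monthly climatologies:

* **annual precipitation** [mm/yr] — sum of the twelve monthly means;
* **biotemperature** [°C] — mean of the monthly average temperatures with
  sub-zero months clamped to 0 °C (annualised over all 12 months);
* **potential evapotranspiration (PET)** [mm/yr] — the Holdridge estimate,
  58.93 × biotemperature;
* **aridity** [-] — annual PET / annual precipitation (>1 means atmospheric
  water demand exceeds supply);

plus a binary **frost indicator** (true where no monthly minimum temperature
drops to or below 0 °C), used to separate temperate from subtropical zones.

Monthly climatologies are represented as :class:`xarray.DataArray` objects
with dimensions ``(month, y, x)`` and a ``month`` coordinate 1..12; derived
annual fields are ``(y, x)`` arrays on the same grid.  All operations require
pre-aligned grids — there is no resampling here.

Because monthly *mean* temperature is often unavailable, it is estimated as
(tmin + tmax)/2 and bias-corrected against a reference period that has all
three series (:func:`bias_correct_tmean`).

Future climates at global-warming levels (1.5/2/3/4 °C above pre-industrial)
are obtained by linear interpolation in time between two bracketing period
climatologies (:func:`interpolate_warming_level`): with centre years x0 < x1
and a target crossing year x,

    Y = (Y0 * (x1 - x) + Y1 * (x - x0)) / (x1 - x0).

Finally, :func:`hlz_classify` maps the parameter fields onto the 38 classic
Holdridge life zones using geometric (log2) class boundaries, shipped as a
versioned CSV table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "PET_PER_BIOTEMP",
    "ARIDITY_CAP",
    "MONTHS",
    "WarmingLevelSpec",
    "monthly_climatology",
    "monthly_mean_estimate",
    "bias_correct_tmean",
    "annual_precipitation",
    "biotemperature",
    "annual_pet",
    "aridity",
    "frost_indicator",
    "interpolate_warming_level",
    "compute_hlz_params",
    "hlz_classify",
    "hlz_zone_table",
    "default_warming_levels",
]

#: Holdridge PET constant: mm of potential evapotranspiration per °C of
#: annual biotemperature.
PET_PER_BIOTEMP = 58.93

#: Aridity assigned where annual precipitation is zero but PET is positive.
#: 2**8 lies beyond the driest Holdridge humidity-province edge, so capping
#: keeps binning finite without merging the cell into any real class.
ARIDITY_CAP = 2.0**8

MONTHS = np.arange(1, 13)


# ---------------------------------------------------------------------------
# containers and validation


def monthly_climatology(values: np.ndarray, name: str = "climate") -> xr.DataArray:
    """Wrap a ``(12, rows, cols)`` array as a monthly climatology DataArray."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] != 12:
        raise ValueError(f"{name}: expected shape (12, rows, cols), got {values.shape}")
    return xr.DataArray(
        values,
        dims=("month", "y", "x"),
        coords={"month": MONTHS},
        name=name,
    )


def _check_monthly(da: xr.DataArray, name: str) -> None:
    if "month" not in da.dims or da.sizes["month"] != 12:
        raise ValueError(f"{name}: monthly climatology must have 12 months")


def _check_aligned(*fields: xr.DataArray) -> None:
    """Reject silently misaligned grids (shape or coordinate mismatch)."""
    ref = fields[0]
    for f in fields[1:]:
        if f.sizes.get("y") != ref.sizes.get("y") or f.sizes.get("x") != ref.sizes.get("x"):
            raise ValueError(
                f"misaligned grids: {dict(ref.sizes)} vs {dict(f.sizes)}"
            )
        for dim in ("y", "x"):
            if dim in ref.coords and dim in f.coords:
                if not np.array_equal(ref[dim].values, f[dim].values):
                    raise ValueError(f"misaligned grids: coordinate {dim!r} differs")


@dataclass(frozen=True)
class WarmingLevelSpec:
    """One global-warming level and the period climatologies that bracket it.

    Parameters
    ----------
    level : float
        Warming level label in °C above pre-industrial (1.5, 2, 3 or 4).
    ssp : str
        Scenario whose IPCC central estimate first crosses the level.
    x : float
        IPCC central-estimate crossing (centre) year.
    x0, x1 : float
        Centre years of the earlier and later period climatologies.
    """

    level: float
    ssp: str
    x: float
    x0: float
    x1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1):
            raise ValueError(f"warming level {self.level}: require x0 < x1")
        if not (self.x0 <= self.x <= self.x1):
            raise ValueError(f"warming level {self.level}: x must lie in [x0, x1]")


def default_warming_levels() -> list[WarmingLevelSpec]:
    """The shipped warming-level table (level, SSP, crossing and centre years)."""
    with resources.files("cropscs.data").joinpath("warming_levels.csv").open() as fh:
        tab = pd.read_csv(fh)
    return [
        WarmingLevelSpec(r.level, r.ssp, r.x, r.x0, r.x1) for r in tab.itertuples()
    ]


# ---------------------------------------------------------------------------
# monthly-temperature plumbing


def monthly_mean_estimate(tmin: xr.DataArray, tmax: xr.DataArray) -> xr.DataArray:
    """Estimate monthly mean temperature as (tmin + tmax) / 2."""
    _check_monthly(tmin, "tmin")
    _check_monthly(tmax, "tmax")
    _check_aligned(tmin, tmax)
    return ((tmin + tmax) / 2.0).rename("tmean")


def bias_correct_tmean(
    tmean_est: xr.DataArray,
    ref_tmean: xr.DataArray,
    ref_tmin: xr.DataArray,
    ref_tmax: xr.DataArray,
) -> xr.DataArray:
    """Correct a (tmin+tmax)/2 estimate with a reference period's known bias.

    The correction adds, per cell and month, the difference between the
    reference period's true monthly mean and its own min/max midpoint:
    ``tmean_est + [ref_tmean - (ref_tmin + ref_tmax)/2]``.  Applying it twice
    adds the bias twice; it is not idempotent.
    """
    for name, f in [
        ("tmean_est", tmean_est),
        ("ref_tmean", ref_tmean),
        ("ref_tmin", ref_tmin),
        ("ref_tmax", ref_tmax),
    ]:
        _check_monthly(f, name)
    _check_aligned(tmean_est, ref_tmean, ref_tmin, ref_tmax)
    bias = ref_tmean - (ref_tmin + ref_tmax) / 2.0
    return (tmean_est + bias).rename("tmean")


# ---------------------------------------------------------------------------
# annual Holdridge parameters


def annual_precipitation(precip: xr.DataArray) -> xr.DataArray:
    """Sum the 12 monthly precipitation means into annual precipitation [mm/yr]."""
    _check_monthly(precip, "precip")
    if bool((precip < 0).any()):
        raise ValueError("negative monthly precipitation")
    return precip.sum("month").rename("annual_precip")


def biotemperature(tmean: xr.DataArray, cap: float | None = None) -> xr.DataArray:
    """Annual biotemperature: mean over 12 months of max(tmean, 0) [°C].

    The divide-by-12 convention (rather than dividing by the number of
    above-zero months) follows the Holdridge framework and keeps
    PET = 58.93 x biotemperature consistent with summing monthly PET values.
    ``cap`` optionally clamps monthly values from above (some life-zone
    variants cap at 30 °C; off by default).
    """
    _check_monthly(tmean, "tmean")
    clamped = tmean.clip(min=0.0)
    if cap is not None:
        clamped = clamped.clip(max=cap)
    return clamped.mean("month").rename("biotemperature")


def annual_pet(tmean: xr.DataArray, cap: float | None = None) -> xr.DataArray:
    """Annual Holdridge PET [mm/yr]: 58.93 x monthly biotemperature, summed.

    Algebraically identical to ``PET_PER_BIOTEMP * biotemperature(tmean)``.
    """
    return (PET_PER_BIOTEMP * biotemperature(tmean, cap=cap)).rename("pet")


def aridity(
    pet: xr.DataArray, annual_precip: xr.DataArray, cap: float = ARIDITY_CAP
) -> xr.DataArray:
    """Aridity index PET / precipitation [-], with a finite dry-limit cap.

    Where precipitation is zero and PET positive the ratio is assigned
    ``cap`` (default 2**8); where both are zero the cell is 0 (cold desert
    with no water demand).
    """
    _check_aligned(pet, annual_precip)
    if bool((pet < 0).any()) or bool((annual_precip < 0).any()):
        raise ValueError("negative PET or precipitation")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pet / annual_precip
    ratio = xr.where(annual_precip > 0, ratio, xr.where(pet > 0, cap, 0.0))
    return ratio.clip(max=cap).rename("aridity")


def frost_indicator(tmin: xr.DataArray) -> xr.DataArray:
    """True where every monthly minimum temperature is strictly above 0 °C."""
    _check_monthly(tmin, "tmin")
    return (tmin.min("month") > 0.0).rename("frost_free")


# ---------------------------------------------------------------------------
# warming-level interpolation


def interpolate_warming_level(
    y0: xr.DataArray | xr.Dataset,
    y1: xr.DataArray | xr.Dataset,
    spec: WarmingLevelSpec,
):
    """Linearly interpolate two period climatologies to a crossing year.

    Weights are (x1-x)/(x1-x0) on the earlier field and (x-x0)/(x1-x0) on
    the later; exact at both endpoints.  Works on any aligned DataArray or
    Dataset pair (monthly stacks or annual parameter bundles alike).
    """
    span = spec.x1 - spec.x0
    if span == 0:
        raise ValueError("degenerate warming-level spec: x0 == x1")
    w0 = (spec.x1 - spec.x) / span
    w1 = (spec.x - spec.x0) / span
    return y0 * w0 + y1 * w1


# ---------------------------------------------------------------------------
# composed parameter bundle


def compute_hlz_params(
    tmin: xr.DataArray,
    tmax: xr.DataArray,
    precip: xr.DataArray,
    reference: tuple[xr.DataArray, xr.DataArray, xr.DataArray] | None = None,
    biotemp_cap: float | None = None,
    aridity_cap: float = ARIDITY_CAP,
) -> xr.Dataset:
    """Compute the full Holdridge parameter bundle from monthly climatologies.

    Parameters
    ----------
    tmin, tmax, precip
        Monthly climatologies on one grid.  For a multi-year baseline the
        caller supplies the pre-averaged monthlies.
    reference
        Optional ``(ref_tmean, ref_tmin, ref_tmax)`` trio from a historical
        period used to bias-correct the (tmin+tmax)/2 mean estimate.

    Returns
    -------
    xarray.Dataset
        Variables ``annual_precip``, ``biotemperature``, ``pet``,
        ``aridity`` and ``frost_free`` on the input grid.
    """
    _check_aligned(tmin, tmax, precip)
    tmean = monthly_mean_estimate(tmin, tmax)
    if reference is not None:
        ref_tmean, ref_tmin, ref_tmax = reference
        tmean = bias_correct_tmean(tmean, ref_tmean, ref_tmin, ref_tmax)
    pr = annual_precipitation(precip)
    bt = biotemperature(tmean, cap=biotemp_cap)
    pet = (PET_PER_BIOTEMP * bt).rename("pet")
    ar = aridity(pet, pr, cap=aridity_cap)
    frost = frost_indicator(tmin)
    ds = xr.Dataset(
        {
            "annual_precip": pr,
            "biotemperature": bt,
            "pet": pet,
            "aridity": ar,
            "frost_free": frost,
        }
    )
    ds.attrs["aridity_cap"] = aridity_cap
    return ds


def threshold_frost(frost_numeric: xr.DataArray) -> xr.DataArray:
    """Re-binarise an interpolated frost indicator (frost-free iff >= 0.5)."""
    return (frost_numeric >= 0.5).rename("frost_free")


# ---------------------------------------------------------------------------
# 38-zone Holdridge classification


def hlz_zone_table() -> pd.DataFrame:
    """The shipped 38-zone edge table (half-open [low, high) intervals).

    Columns: zone_id 1..38, zone_name, biotemperature class bounds [°C],
    annual-precipitation class bounds [mm/yr] (log2-spaced), and a
    ``frost_free`` flag that is 0/1 only in the 12-24 °C band, where frost
    separates warm-temperate from subtropical zones.
    """
    with resources.files("cropscs.data").joinpath("hlz_zones.csv").open() as fh:
        tab = pd.read_csv(fh)
    return tab


def hlz_classify(params: xr.Dataset) -> xr.DataArray:
    """Assign each cell one of the 38 Holdridge life zones.

    Classification is on the biotemperature class (log2 edges 1.5, 3, 6, 12,
    24 °C) and the annual-precipitation class (log2 edges 125 ... 8000 mm/yr),
    with the frost indicator splitting the 12-24 °C band into warm-temperate
    (frosty) and subtropical (frost-free) rows; aridity classes follow from
    these two through PET = 58.93 x biotemperature.  Intervals are half-open
    [low, high).  Cells with non-finite parameters get zone 0 (unclassified).
    """
    tab = hlz_zone_table()
    bt = params["biotemperature"].values
    pr = params["annual_precip"].values
    frost = params["frost_free"].values.astype(bool)

    zone = np.zeros(bt.shape, dtype=np.int16)
    finite = np.isfinite(bt) & np.isfinite(pr)
    for row in tab.itertuples():
        mask = (
            finite
            & (bt >= row.bt_low)
            & (bt < row.bt_high)
            & (pr >= row.precip_low)
            & (pr < row.precip_high)
        )
        if not np.isnan(row.frost_free):
            mask &= frost == bool(row.frost_free)
        zone[mask] = row.zone_id
    return xr.DataArray(
        zone, dims=params["biotemperature"].dims, coords=params["biotemperature"].coords,
        name="hlz_zone",
    )
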