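"""Ensemble projection of SCS membership across GCMs and warming levels.

Future niche membership is evaluated independently for every general
circulation model (GCM) in the ensemble and every global-warming level, then
combined by a majority vote: a cell is within a crop's niche at a level if
at least half of the models say so (inclusive — 4 of 8 suffices).  Ensemble
spread of scalar summaries is reported as the median with the 25th and 75th
percentiles, using linear-interpolation quantiles.

Membership cubes are boolean :class:`xarray.DataArray` objects with a
``gcm`` dimension (and optionally ``crop`` / ``level``); cells off the
analysis extent are masked out of every aggregate.
"""

from __future__ import annotations

import math

import numpy as np
import xarray as xr

from .climate import _check_aligned
from .scs import SCSDefinition, scs_membership

__all__ = [
    "ensemble_membership",
    "majority_vote",
    "ensemble_quantiles",
    "vote_threshold",
]


def vote_threshold(n_gcms: int) -> int:
    """Votes needed for consensus: ceil(n/2) ("at least half", inclusive)."""
    if n_gcms < 1:
        raise ValueError("need at least one ensemble member")
    return math.ceil(n_gcms / 2)


def ensemble_membership(
    scs: SCSDefinition,
    gcm_params: dict[str, xr.Dataset],
    extent_mask: xr.DataArray | None = None,
) -> xr.DataArray:
    """Per-GCM niche membership for one crop at one warming level.

    Parameters
    ----------
    scs
        The crop's delineated niche.
    gcm_params
        Mapping GCM name -> Holdridge parameter bundle at the level.
    extent_mask
        Optional boolean analysis extent (crop production area or total
        cropland); off-extent cells are forced False and should be treated
        as undefined by downstream aggregations.

    Returns
    -------
    xarray.DataArray
        Boolean, dims ``(gcm, y, x)``.
    """
    if not gcm_params:
        raise ValueError("empty GCM ensemble")
    fields = []
    names = []
    ref = None
    for name, params in gcm_params.items():
        if ref is None:
            ref = params["annual_precip"]
        else:
            _check_aligned(ref, params["annual_precip"])
        member = scs_membership(params, scs)
        if extent_mask is not None:
            _check_aligned(ref, extent_mask)
            member = member & extent_mask
        fields.append(member)
        names.append(name)
    cube = xr.concat(fields, dim="gcm")
    cube = cube.assign_coords(gcm=names)
    return cube.rename("within_scs")


def majority_vote(members: xr.DataArray, dim: str = "gcm") -> xr.DataArray:
    """Consensus membership: within iff >= ceil(n/2) members are within."""
    n = members.sizes[dim]
    thresh = vote_threshold(n)
    return (members.sum(dim) >= thresh).rename("consensus")


def ensemble_quantiles(values) -> dict[str, float]:
    """Median and 25th/75th percentiles of per-GCM scalar estimates.

    Linear interpolation between order statistics (the numpy default).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty ensemble value list")
    p25, med, p75 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "p25": float(p25), "p75": float(p75)}
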