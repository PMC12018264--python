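"""Safe Climatic Space (SCS) delineation and membership.

A crop's Safe Climatic Space is its empirical climatic niche: the set of
climate-space bins occupied by the grid cells producing the top 95% of the
crop's current output.  Climate space is the four-axis product of annual
precipitation x biotemperature x aridity (each discretised on log2-spaced
bin edges mirroring the geometric Holdridge class structure) and the binary
frost indicator.  Membership of any climate in the niche is then a pure
bin-set lookup — no convex hull or density model is involved, so the
envelope is exactly the union of occupied bins.

Using the top-95% ("major production") rule excludes marginally suitable
climates from the niche; the complementary lowest-5% contributors are the
"marginal production" cells used by the diversity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .climate import _check_aligned

__all__ = [
    "ClimateBinning",
    "SCSDefinition",
    "CropLayer",
    "default_binning",
    "select_major_cells",
    "select_marginal_cells",
    "delineate_scs",
    "scs_membership",
]

#: Holdridge class bases and spans used for the default log2 binning.
_PRECIP_BASE, _PRECIP_OCTAVES = 62.5, 8      # 62.5 .. 16000 mm/yr
_BIOTEMP_BASE, _BIOTEMP_OCTAVES = 1.5, 4     # 1.5 .. 24 °C
_ARIDITY_BASE, _ARIDITY_OCTAVES = 0.125, 8   # 1/8 .. 32


def _log2_edges(base: float, octaves: int, bins_per_class: int) -> np.ndarray:
    steps = np.arange(octaves * bins_per_class + 1, dtype=float)
    return base * 2.0 ** (steps / bins_per_class)


@dataclass(frozen=True)
class ClimateBinning:
    """Discretisation of the (precip, biotemperature, aridity) climate space.

    Each axis is a strictly increasing edge list; values below the first or
    above the last edge fall into open outer bins, so every finite value maps
    to exactly one bin.  The frost flag is a full fourth (boolean) axis.
    """

    precip_edges: np.ndarray
    biotemp_edges: np.ndarray
    aridity_edges: np.ndarray
    bins_per_class: int | None = None

    def __post_init__(self) -> None:
        for name in ("precip_edges", "biotemp_edges", "aridity_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError(f"{name}: need at least 2 edges")
            if not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name}: edges must be strictly increasing")
            object.__setattr__(self, name, edges)

    def bin_indices(
        self, params: xr.Dataset
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell bin index on each axis plus a finite-validity mask."""
        pr = params["annual_precip"].values
        bt = params["biotemperature"].values
        ar = params["aridity"].values
        frost = params["frost_free"].values.astype(bool)
        valid = np.isfinite(pr) & np.isfinite(bt) & np.isfinite(ar)
        ip = np.digitize(pr, self.precip_edges)
        ib = np.digitize(bt, self.biotemp_edges)
        ia = np.digitize(ar, self.aridity_edges)
        return ip, ib, ia, frost.astype(np.int64), valid

    def encode(self, ip, ib, ia, frost) -> np.ndarray:
        """Pack per-axis bin indices into one integer key per cell."""
        nb = self.biotemp_edges.size + 1
        na = self.aridity_edges.size + 1
        return ((np.asarray(ip) * nb + ib) * na + ia) * 2 + frost

    def decode(self, key: int) -> tuple[int, int, int, int]:
        nb = self.biotemp_edges.size + 1
        na = self.aridity_edges.size + 1
        key, frost = divmod(int(key), 2)
        key, ia = divmod(key, na)
        ip, ib = divmod(key, nb)
        return ip, ib, ia, frost

    def to_dict(self) -> dict:
        return {
            "precip_edges": self.precip_edges.tolist(),
            "biotemp_edges": self.biotemp_edges.tolist(),
            "aridity_edges": self.aridity_edges.tolist(),
            "bins_per_class": self.bins_per_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClimateBinning":
        return cls(
            np.asarray(d["precip_edges"]),
            np.asarray(d["biotemp_edges"]),
            np.asarray(d["aridity_edges"]),
            d.get("bins_per_class"),
        )


def default_binning(bins_per_class: int = 2) -> ClimateBinning:
    """Log2 binning aligned with the Holdridge classes.

    ``bins_per_class`` geometric sub-bins per Holdridge class per axis
    (default 2).  Resolution matters for the niche envelope, so it is
    recorded in the binning and in every SCS definition's provenance.
    """
    if bins_per_class < 1:
        raise ValueError("bins_per_class must be >= 1")
    return ClimateBinning(
        _log2_edges(_PRECIP_BASE, _PRECIP_OCTAVES, bins_per_class),
        _log2_edges(_BIOTEMP_BASE, _BIOTEMP_OCTAVES, bins_per_class),
        _log2_edges(_ARIDITY_BASE, _ARIDITY_OCTAVES, bins_per_class),
        bins_per_class=bins_per_class,
    )


@dataclass
class CropLayer:
    """Per-crop production [t/cell] and physical cropland area [ha/cell]."""

    crop_id: str
    production: xr.DataArray
    physical_area: xr.DataArray
    food_flag: bool = True
    group: str | None = None

    def __post_init__(self) -> None:
        _check_aligned(self.production, self.physical_area)
        if bool((self.production < 0).any()) or bool((self.physical_area < 0).any()):
            raise ValueError(f"{self.crop_id}: negative production or area")


@dataclass
class SCSDefinition:
    """A crop's climatic niche as a set of occupied climate-space bins.

    ``occupied`` holds (precip_bin, biotemp_bin, aridity_bin, frost_flag)
    tuples; ``provenance`` records the production share actually captured by
    the delineation cells, the cell counts, and the binning resolution.
    """

    crop_id: str
    binning: ClimateBinning
    occupied: frozenset
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "crop_id": self.crop_id,
                "binning": self.binning.to_dict(),
                "occupied": sorted(list(t) for t in self.occupied),
                "provenance": self.provenance,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SCSDefinition":
        d = json.loads(text)
        return cls(
            d["crop_id"],
            ClimateBinning.from_dict(d["binning"]),
            frozenset(tuple(t) for t in d["occupied"]),
            d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# major / marginal production cells


def _ranked_flat(production: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    flat = production.values.ravel()  # row-major
    if not np.isfinite(flat).all():
        raise ValueError("non-finite production")
    total = flat.sum()
    if total <= 0:
        raise ValueError("all-zero production: cannot rank cells")
    # stable sort on descending production -> ties broken row-major
    order = np.argsort(-flat, kind="stable")
    return flat, order


def select_major_cells(production: xr.DataArray, share: float = 0.95) -> xr.DataArray:
    """Cells producing the top ``share`` of a crop's total output.

    Cells are ranked by production (descending, ties row-major) and the
    smallest prefix whose cumulative production reaches ``share`` of the
    total is selected — the crossing cell is included, so the realised share
    is >= the nominal one.  Zero-production cells are never selected.
    """
    if not (0 < share <= 1):
        raise ValueError("share must be in (0, 1]")
    flat, order = _ranked_flat(production)
    csum = np.cumsum(flat[order])
    total = csum[-1]
    k = int(np.searchsorted(csum, share * total)) + 1
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[chosen] = True
    return xr.DataArray(
        mask.reshape(production.shape),
        dims=production.dims,
        coords=production.coords,
        name="major_cells",
    )


def select_marginal_cells(
    production: xr.DataArray,
    share: float = 0.05,
    cropland_mask: xr.DataArray | None = None,
) -> xr.DataArray:
    """Cells contributing the lowest ``share`` of a crop's total output.

    The complement, within positive-production cells, of the major cells at
    share ``1 - share``.  When ``cropland_mask`` is given, zero-production
    cropland cells are included too ("marginal or no production").
    """
    major = select_major_cells(production, 1.0 - share) if share < 1.0 else None
    positive = production > 0
    marginal = positive & ~major if major is not None else positive
    if cropland_mask is not None:
        marginal = marginal | (cropland_mask & ~positive)
    return marginal.rename("marginal_cells")


# ---------------------------------------------------------------------------
# delineation and membership


def delineate_scs(
    crop: CropLayer,
    baseline_params: xr.Dataset,
    binning: ClimateBinning | None = None,
    share: float = 0.95,
) -> SCSDefinition:
    """Delineate a crop's SCS from its major-production cells' baseline climate.

    The occupied set is every climate-space bin containing at least one
    major-production cell with finite parameters; cells with non-finite
    parameters are excluded and counted in the provenance.
    """
    if binning is None:
        binning = default_binning()
    _check_aligned(crop.production, baseline_params["annual_precip"])
    major = select_major_cells(crop.production, share).values
    ip, ib, ia, frost, valid = binning.bin_indices(baseline_params)
    use = major & valid
    occupied = frozenset(
        zip(ip[use].tolist(), ib[use].tolist(), ia[use].tolist(), frost[use].tolist())
    )
    total = float(crop.production.values.sum())
    captured = float(crop.production.values[use].sum())
    return SCSDefinition(
        crop.crop_id,
        binning,
        occupied,
        provenance={
            "delineation_share": share,
            "captured_share": captured / total,
            "n_cells": int(use.sum()),
            "n_excluded_nonfinite": int((major & ~valid).sum()),
            "bins_per_class": binning.bins_per_class,
        },
    )


def scs_membership(params: xr.Dataset, scs: SCSDefinition) -> xr.DataArray:
    """Boolean field: does each cell's climate fall in an occupied SCS bin?

    Cells with non-finite parameters are outside.  Vectorised as an integer
    key lookup against the encoded occupied set.
    """
    b = scs.binning
    ip, ib, ia, frost, valid = b.bin_indices(params)
    keys = b.encode(ip, ib, ia, frost)
    occ = np.fromiter(
        (b.encode(*t) for t in scs.occupied), dtype=np.int64, count=len(scs.occupied)
    )
    within = np.isin(keys, occ) & valid
    template = params["annual_precip"]
    return xr.DataArray(
        within, dims=template.dims, coords=template.coords, name="within_scs"
    )
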