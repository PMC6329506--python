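"""Grazing-energy supply: convert NPP and land cover to an annual energy raster.

The supply map answers "how much metabolizable energy could livestock obtain
from each pixel in a year?".  Total NPP (gC/m²/yr) is converted to dry matter
with a fixed carbon fraction, then to energy with a cover-dependent energy
density.  On cropland only the post-harvest residue fraction of the aboveground
biomass is available; forest, water, ice, artificial surfaces and nature
preserves are excluded outright.  Bare soil is grazeable and treated as
grassland (low NPP, but grazing does occur there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import ValidationError
from .grid import CoverClass, CoverRaster, Grid, NPPRaster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SupplyParams:
    """Energy-conversion coefficients of the supply model.

    carbon_to_dm
        Carbon fraction of dry matter (gC per gDM); NPP / carbon_to_dm is
        dry-matter production.
    grass_energy, residue_energy
        Metabolizable energy density of grassland herbage and of crop residue
        (MJ per kgDM).
    harvest_index
        Grain mass as a fraction of total aboveground crop biomass (wheat).
    crop_aboveground_frac
        Fraction of total crop biomass that is aboveground at harvest.
    grass_aboveground_npp_frac
        Aboveground share of total grassland NPP.
    max_aboveground_offtake
        Fraction of aboveground production that can be removed sustainably.
    """

    carbon_to_dm: float = 0.47
    grass_energy: float = 8.6
    residue_energy: float = 6.0
    harvest_index: float = 0.48
    crop_aboveground_frac: float = 0.90
    grass_aboveground_npp_frac: float = 0.77
    max_aboveground_offtake: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "carbon_to_dm",
            "harvest_index",
            "crop_aboveground_frac",
            "grass_aboveground_npp_frac",
            "max_aboveground_offtake",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.grass_energy <= 0 or self.residue_energy <= 0:
            raise ValidationError("energy densities must be > 0")

    @property
    def max_sustainable_offtake(self) -> float:
        """Maximum sustainable off-take as a fraction of *total* NPP
        (aboveground share × sustainable aboveground removal)."""
        return self.max_aboveground_offtake * self.grass_aboveground_npp_frac


class UsableClass(IntEnum):
    """Simplified per-pixel usability recorded on the supply raster."""

    EXCLUDED = 0
    GRASSLAND = 1
    CROPLAND = 2


@dataclass
class SupplyRaster:
    """Annual grazeable energy density (MJ/m²) plus per-pixel usability class."""

    grid: Grid
    energy: np.ndarray = field(repr=False)
    usable: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.usable = np.asarray(self.usable, dtype=np.int8)
        if self.energy.shape != self.grid.shape or self.usable.shape != self.grid.shape:
            raise ValidationError("supply arrays must match grid shape")

    def pixel_energy(self) -> np.ndarray:
        """Total energy per pixel in MJ (density × cell area)."""
        return self.energy * self.grid.cell_area


def build_supply(npp: NPPRaster, cover: CoverRaster, params: SupplyParams | None = None) -> SupplyRaster:
    """Merge the NPP and land-cover rasters into the grazing-supply raster.

    Grassland and bare pixels get the grassland energy pathway
    ``(npp / carbon_to_dm) / 1000 × grass_energy`` (MJ/m²); cropland pixels get
    the residue pathway
    ``(npp / carbon_to_dm) / 1000 × crop_aboveground_frac × (1 − harvest_index)
    × residue_energy``; all other classes are excluded with zero energy.

    Missing NPP on a grazeable pixel is treated as zero energy with a logged
    warning rather than an error, so marginal map edges stay usable.
    """
    params = params or SupplyParams()
    npp.grid.require_same_geometry(cover.grid, "NPP/cover")

    values = npp.values
    missing = ~np.isfinite(values)
    cls = cover.classes

    grass = (cls == CoverClass.GRASSLAND) | (cls == CoverClass.BARE)
    crop = cls == CoverClass.CROPLAND

    n_missing_usable = int(np.count_nonzero(missing & (grass | crop)))
    if n_missing_usable:
        logger.warning(
            "%d grazeable pixels have missing NPP; treating them as zero energy",
            n_missing_usable,
        )

    dm_kg = np.where(missing, 0.0, values) / params.carbon_to_dm / 1000.0  # kgDM/m²
    energy = np.zeros(npp.grid.shape, dtype=float)
    energy[grass] = dm_kg[grass] * params.grass_energy
    energy[crop] = (
        dm_kg[crop]
        * params.crop_aboveground_frac
        * (1.0 - params.harvest_index)
        * params.residue_energy
    )

    usable = np.full(npp.grid.shape, int(UsableClass.EXCLUDED), dtype=np.int8)
    usable[grass] = int(UsableClass.GRASSLAND)
    usable[crop] = int(UsableClass.CROPLAND)
    return SupplyRaster(npp.grid, energy, usable)


def total_supply(supply: SupplyRaster, usable_filter: UsableClass | None = None) -> float:
    """Total available energy in MJ, optionally restricted to one usability class."""
    if usable_filter is None:
        mask = supply.usable != int(UsableClass.EXCLUDED)
    else:
        mask = supply.usable == int(usable_filter)
    return float(supply.energy[mask].sum() * supply.grid.cell_area)
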