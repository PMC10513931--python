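"""Consumption-side footprint pipeline.

For a consuming region with final-demand column d, the consumption
footprint per land type is ``F_l @ L @ d`` with ``L = (I - A)^-1``.  Two
attributions of that scalar are used:

* producer side, ``F_l * (L @ d)``: where in the world the bioproductive
  area is appropriated — feeds the domestic / intra-group (ROE) /
  extra-group (ROW) origin decomposition;
* demand side, ``(F_l @ L) * d``: which demanded sector (and hence, through
  a sector-to-COICOP concordance, which household consumption category)
  drives it — feeds the food-footprint extraction.

Both sum to the same total; the full tensor ``F_l[i] * L[i, j] * d[j]``
resolves category x land type x producing region jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_accounts import LAND_TYPES
from .extension_builder import ExtensionTable
from .mrio_model import (
    MRIOWorld,
    leontief_inverse,
    technical_coefficients,
    total_requirements_footprint,
)

_REL_TOL = 1e-9


@dataclass
class FootprintFlows:
    """A region's consumption footprint resolved by land type x producer.

    ``cells[l, r, s]`` is the gha of land type ``l`` appropriated in sector
    ``s`` of producing region ``r`` to serve the consumer's final demand.
    """

    consumer: str
    regions: list[str]
    sectors: list[str]
    cells: np.ndarray  # (n_land, R, S)
    land_types: tuple[str, ...] = LAND_TYPES

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, float)
        expected = (len(self.land_types), len(self.regions), len(self.sectors))
        if self.cells.shape != expected:
            raise ValueError(f"cells must be {expected}, got {self.cells.shape}")
        if np.any(self.cells < -1e-12):
            raise ValueError("footprint cells must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def by_land_type(self) -> pd.Series:
        return pd.Series(self.cells.sum(axis=(1, 2)), index=list(self.land_types))

    def by_producing_region(self) -> pd.Series:
        return pd.Series(self.cells.sum(axis=(0, 2)), index=self.regions)


@dataclass(frozen=True)
class OriginShares:
    """Fractions of a footprint produced domestically, in the group (ROE), and outside (ROW)."""

    domestic: float
    intra_group: float
    extra_group: float

    def __post_init__(self) -> None:
        total = self.domestic + self.intra_group + self.extra_group
        for name, v in (
            ("domestic", self.domestic),
            ("intra_group", self.intra_group),
            ("extra_group", self.extra_group),
        ):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name} share must be in [0, 1], got {v}")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin shares must sum to 1, got {total}")


@dataclass
class CoicopConcordance:
    """Sector-to-COICOP shares: each demanded sector's footprint is spread
    over consumption categories; rows must sum to 1 (mass conservation)."""

    shares: pd.DataFrame  # RS sector labels x C categories
    food_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.food_categories = frozenset(self.food_categories)
        if np.any(self.shares.to_numpy() < 0):
            raise ValueError("concordance shares must be nonnegative")
        sums = self.shares.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > _REL_TOL):
            bad = self.shares.index[np.abs(sums - 1.0) > _REL_TOL][:5].tolist()
            raise ValueError(f"concordance rows must sum to 1; offending sectors {bad}")
        unknown = self.food_categories - set(self.shares.columns)
        if unknown:
            raise ValueError(f"food_categories not in concordance: {sorted(unknown)}")

    @property
    def categories(self) -> list[str]:
        return list(self.shares.columns)


def run_efmrio(world: MRIOWorld, ext: ExtensionTable, consumer: str) -> FootprintFlows:
    """Consumption footprint of one region, by land type x producing region x sector."""
    if consumer not in world.regions:
        raise KeyError(f"unknown consumer region {consumer!r}")
    A = technical_coefficients(world)
    d = world.D[:, world.regions.index(consumer)]
    attribution = total_requirements_footprint(ext.F, A, d)  # (n_land, RS)
    cells = attribution.reshape(len(ext.land_types), world.n_regions, world.n_sectors)
    # Tiny negative round-off from the linear solve is clipped.
    cells = np.where(np.abs(cells) < 1e-15, 0.0, cells)
    return FootprintFlows(
        consumer=consumer,
        regions=list(world.regions),
        sectors=list(world.sectors),
        cells=cells,
        land_types=ext.land_types,
    )


def demand_side_footprints(
    world: MRIOWorld, ext: ExtensionTable, consumer: str
) -> np.ndarray:
    """Footprint by demanded sector: ``(F @ L)[l, j] * d[j]``, shape (n_land, RS)."""
    A = technical_coefficients(world)
    L = leontief_inverse(A)
    d = world.D[:, world.regions.index(consumer)]
    return (ext.F @ L) * d[np.newaxis, :]


def footprint_tensor(
    world: MRIOWorld, ext: ExtensionTable, consumer: str
) -> np.ndarray:
    """Full attribution tensor ``T[l, i, j] = F[l, i] * L[i, j] * d[j]``.

    Summing over j recovers the producer attribution, over i the demand
    attribution; over both, the per-land-type total.
    """
    A = technical_coefficients(world)
    L = leontief_inverse(A)
    d = world.D[:, world.regions.index(consumer)]
    return ext.F[:, :, np.newaxis] * L[np.newaxis, :, :] * d[np.newaxis, np.newaxis, :]


def decompose_origin(flows: FootprintFlows, group_members: set[str]) -> OriginShares:
    """Split a footprint by producing region into domestic / ROE / ROW shares."""
    total = flows.total
    if total <= 0:
        raise ValueError(
            f"origin shares undefined: total footprint of {flows.consumer!r} is {total}"
        )
    by_region = flows.by_producing_region()
    domestic = float(by_region.get(flows.consumer, 0.0))
    intra = float(
        sum(v for r, v in by_region.items() if r in group_members and r != flows.consumer)
    )
    extra = total - domestic - intra
    return OriginShares(domestic / total, intra / total, max(extra, 0.0) / total)


def recategorize_coicop(
    sector_footprints: pd.Series | np.ndarray, conc: CoicopConcordance
) -> pd.Series:
    """Re-categorize demand-side sector footprints into COICOP categories.

    ``category_c = sum_s footprint_s * share_sc``; conserves the total gha.
    """
    if isinstance(sector_footprints, pd.Series):
        missing = set(sector_footprints.index) - set(conc.shares.index)
        if missing:
            raise ValueError(f"sectors missing from concordance: {sorted(missing)[:5]}")
        fp = sector_footprints.reindex(conc.shares.index).fillna(0.0).to_numpy()
    else:
        fp = np.asarray(sector_footprints, float)
        if fp.shape[0] != conc.shares.shape[0]:
            raise ValueError(
                f"{fp.shape[0]} sector footprints but concordance has "
                f"{conc.shares.shape[0]} rows"
            )
    values = conc.shares.to_numpy().T @ fp
    return pd.Series(values, index=conc.categories, name="gha")


@dataclass(frozen=True)
class FoodFootprint:
    """Per-capita food footprint (FF) and its share of the total footprint."""

    ff_per_capita: float
    total_ef_per_capita: float

    @property
    def ff_share(self) -> float:
        return self.ff_per_capita / self.total_ef_per_capita if self.total_ef_per_capita else 0.0


def food_footprint(
    coicop_footprints: pd.Series, conc: CoicopConcordance, population: float
) -> FoodFootprint:
    """Sum COICOP food categories and divide by population (gha/person)."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    food = float(
        sum(coicop_footprints.get(c, 0.0) for c in conc.food_categories)
    )
    total = float(coicop_footprints.sum())
    return FoodFootprint(food / population, total / population)


def read_concordance(path, food_categories=()) -> CoicopConcordance:
    """Read concordance_coicop.csv (sector, category, share) into matrix form."""
    df = pd.read_csv(path)
    missing = {"sector", "category", "share"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    shares = df.pivot_table(
        index="sector", columns="category", values="share", fill_value=0.0, sort=False
    )
    return CoicopConcordance(shares=shares, food_categories=frozenset(food_categories))
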