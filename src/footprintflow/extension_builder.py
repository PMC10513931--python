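"""Build environmental extension tables from per-region footprints of production.

One extension table exists per land type; together they form a 6 x RS matrix
``E`` of direct production footprints (gha) allocated to economic sectors,
and its intensity form ``F = E @ diag(x)^-1`` (gha per currency) used in the
Leontief footprint computation.

Allocation rules, per region:

* cropland EF_P is split over the cropland sector group, grazing over the
  grazing group, by within-group weights (default: each sector's share of
  gross output within the group);
* forest and fishing EF_P go wholly to their single sectors;
* carbon EF_P is split over all sectors by their share of regional CO2
  emissions;
* built-up EF_P is split over all sectors by their share of regional value
  added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_accounts import LAND_TYPES
from .mrio_model import MRIOWorld

_SHARE_TOL = 1e-9


class AllocationError(ValueError):
    """Extension allocation cannot be performed (missing data or zero weights)."""


@dataclass
class SectorAllocationScheme:
    """How each land type's production footprint maps to sectors.

    Sector indices are within-region (0-based, < S) and apply identically to
    every region.  ``emission_share`` and ``value_added_share`` are R x S
    arrays whose rows sum to 1.  ``within_group_weights`` optionally fixes
    the split inside the cropland/grazing groups (one weight per group
    member, shared across regions); when absent, gross-output shares within
    the group are used.

    ``strict=False`` relaxes the group-disjointness requirement for
    degenerate worlds with fewer sectors than land-type groups.
    """

    cropland_sectors: Sequence[int]
    grazing_sectors: Sequence[int]
    forest_sector: int
    fishing_sector: int
    emission_share: np.ndarray
    value_added_share: np.ndarray
    within_group_weights: Mapping[str, Sequence[float]] | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        self.cropland_sectors = list(self.cropland_sectors)
        self.grazing_sectors = list(self.grazing_sectors)
        self.emission_share = np.atleast_2d(np.asarray(self.emission_share, float))
        self.value_added_share = np.atleast_2d(np.asarray(self.value_added_share, float))
        groups = [
            self.cropland_sectors,
            self.grazing_sectors,
            [self.forest_sector],
            [self.fishing_sector],
        ]
        if self.strict:
            seen: set[int] = set()
            for g in groups:
                if seen & set(g):
                    raise ValueError(f"sector groups must be disjoint, overlap at {sorted(seen & set(g))}")
                seen |= set(g)
        for name, share in (
            ("emission_share", self.emission_share),
            ("value_added_share", self.value_added_share),
        ):
            if np.any(share < 0):
                raise ValueError(f"{name} must be nonnegative")
            sums = share.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _SHARE_TOL):
                raise ValueError(f"{name} rows must sum to 1 (got {sums})")
        if self.within_group_weights is not None:
            for key, w in self.within_group_weights.items():
                w = np.asarray(w, float)
                if np.any(w < 0):
                    raise ValueError(f"within_group_weights[{key!r}] must be nonnegative")

    def group(self, land_type: str) -> list[int]:
        return {
            "cropland": list(self.cropland_sectors),
            "grazing": list(self.grazing_sectors),
            "forest": [self.forest_sector],
            "fishing": [self.fishing_sector],
        }[land_type]


@dataclass
class ExtensionTable:
    """Direct production footprints by land type x sector.

    ``E`` holds gha (rows ordered as :data:`~footprintflow.core_accounts.LAND_TYPES`),
    ``F`` the per-currency intensities used in the footprint model.
    """

    E: np.ndarray
    F: np.ndarray
    land_types: tuple[str, ...] = LAND_TYPES

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, float)
        self.F = np.asarray(self.F, float)
        if self.E.shape != self.F.shape or self.E.shape[0] != len(self.land_types):
            raise ValueError("E and F must both be (n_land_types, RS)")
        if np.any(self.E < 0):
            raise ValueError("E must be nonnegative")

    def to_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=list(self.land_types), columns=list(labels))


def _group_weights(
    scheme: SectorAllocationScheme,
    land_type: str,
    group: Sequence[int],
    x_region: np.ndarray,
) -> np.ndarray:
    if scheme.within_group_weights and land_type in scheme.within_group_weights:
        w = np.asarray(scheme.within_group_weights[land_type], float)
        if len(w) != len(group):
            raise AllocationError(
                f"{land_type}: {len(group)} group members but {len(w)} weights"
            )
    else:
        w = x_region[list(group)]
    return w


def build_extension(
    efp: pd.DataFrame | Mapping[tuple[str, str], float],
    scheme: SectorAllocationScheme,
    world: MRIOWorld,
) -> ExtensionTable:
    """Allocate per-region EF_P by land type to sectors and normalize.

    Parameters
    ----------
    efp
        Either a tidy DataFrame with columns (region, land_type, gha) or a
        mapping ``(region, land_type) -> gha``.  All six land types must be
        present for every region (zeros allowed).
    """
    if isinstance(efp, pd.DataFrame):
        table = {(r.region, r.land_type): float(r.gha) for r in efp.itertuples()}
    else:
        table = {k: float(v) for k, v in efp.items()}

    R, S = world.n_regions, world.n_sectors
    if scheme.emission_share.shape != (R, S):
        raise AllocationError(
            f"emission_share must be ({R}, {S}), got {scheme.emission_share.shape}"
        )
    if scheme.value_added_share.shape != (R, S):
        raise AllocationError(
            f"value_added_share must be ({R}, {S}), got {scheme.value_added_share.shape}"
        )

    E = np.zeros((len(LAND_TYPES), R * S))
    for ri, region in enumerate(world.regions):
        base = ri * S
        x_region = world.x[base : base + S]
        for li, lt in enumerate(LAND_TYPES):
            if (region, lt) not in table:
                raise AllocationError(f"missing EF_P for region {region!r}, land type {lt!r}")
            total = table[(region, lt)]
            if total < 0:
                raise AllocationError(f"EF_P must be >= 0 ({region}/{lt}: {total})")
            if total == 0.0:
                continue
            if lt == "carbon":
                E[li, base : base + S] += total * scheme.emission_share[ri]
            elif lt == "builtup":
                E[li, base : base + S] += total * scheme.value_added_share[ri]
            else:
                group = scheme.group(lt)
                w = _group_weights(scheme, lt, group, x_region)
                wsum = w.sum()
                if wsum <= 0:
                    raise AllocationError(
                        f"{region}/{lt}: group weights sum to 0 but EF_P = {total} gha"
                    )
                for g, wg in zip(group, w / wsum):
                    E[li, base + g] += total * wg
    F = intensity_form(E, world.x)
    return ExtensionTable(E=E, F=F)


def intensity_form(E: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Normalize an extension matrix per unit of sector output: F = E / x.

    Columns of zero-output sectors are zero; a positive footprint in such a
    column has no output to attach to and triggers a stranded-footprint
    warning.
    """
    E = np.asarray(E, float)
    x = np.asarray(x, float)
    if E.ndim != 2 or E.shape[1] != x.shape[0]:
        raise ValueError(f"E columns ({E.shape}) must match x length ({x.shape})")
    zero = x <= 0
    stranded = zero[np.newaxis, :] & (E > 0)
    if np.any(stranded):
        cells = list(zip(*np.nonzero(stranded)))
        warnings.warn(
            f"stranded footprint: E > 0 in zero-output sectors at cells {cells[:10]}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(zero[np.newaxis, :], 0.0, E / np.where(zero, 1.0, x)[np.newaxis, :])
    return F


def read_efp(path) -> pd.DataFrame:
    """Read efp.csv with columns region, land_type, gha."""
    df = pd.read_csv(path)
    missing = {"region", "land_type", "gha"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
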