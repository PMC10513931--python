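"""Dietary footprint intensities and the FBS -> CPC -> COICOP concordance.

Food-balance-sheet (FBS) items report per-capita supply in kg and kcal per
year.  Some FBS items bundle several derived products ("tomatoes and
products" covers tomato, tomato juice, tomato paste, peeled tomatoes) that
belong to different COICOP consumption categories; such items are split via
the Central Product Classification (CPC), allocating supply in proportion to
each derivative's share of world imports.  The import mix on the production
side is taken as a proxy for the consumption mix — a stated first
approximation, applied without correction.

The footprint intensity of a diet divides the per-capita food footprint by
per-capita supply: gha/kg and gha per 1,000 kcal, the latter also expressed
in global m2 per 1,000 kcal (1 gha = 10,000 global m2) for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core_accounts import GM2_PER_GHA


@dataclass(frozen=True)
class FoodSupplyItem:
    """Per-capita supply of one FBS item, e.g. ``"#2601 tomatoes and products"``."""

    fbs_code: str
    kg_per_capita_yr: float
    kcal_per_capita_yr: float

    def __post_init__(self) -> None:
        if self.kg_per_capita_yr < 0 or self.kcal_per_capita_yr < 0:
            raise ValueError(f"{self.fbs_code}: supply quantities must be >= 0")


@dataclass(frozen=True)
class CpcChild:
    """One CPC derivative of an FBS item with its world import quantity."""

    cpc_code: str
    coicop_category: str
    world_import_qty: float

    def __post_init__(self) -> None:
        if self.world_import_qty < 0:
            raise ValueError(f"{self.cpc_code}: import quantity must be >= 0")


@dataclass(frozen=True)
class CpcSplit:
    """CPC-level decomposition of an FBS item into COICOP categories."""

    fbs_code: str
    children: tuple[CpcChild, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError(f"{self.fbs_code}: split needs at least one child")


@dataclass(frozen=True)
class IntensityRecord:
    """Footprint intensity of a diet, food category or item."""

    key: str
    gha_per_kg: float
    gha_per_1000kcal: float

    @property
    def gm2_per_1000kcal(self) -> float:
        return self.gha_per_1000kcal * GM2_PER_GHA


def split_shares(split: CpcSplit) -> dict[str, float]:
    """Allocation shares by COICOP category from world import quantities.

    ``share_c = import_c / sum(imports)``, summed over children in the same
    category; scale-invariant in the import quantities.
    """
    total = sum(c.world_import_qty for c in split.children)
    if total <= 0:
        raise ValueError(
            f"{split.fbs_code}: all world import quantities are zero; "
            "no basis for allocation"
        )
    out: dict[str, float] = {}
    for child in split.children:
        out[child.coicop_category] = (
            out.get(child.coicop_category, 0.0) + child.world_import_qty / total
        )
    return out


def aggregate_supply(
    items: Iterable[FoodSupplyItem], splits: Mapping[str, CpcSplit]
) -> pd.DataFrame:
    """Sum per-capita supply into COICOP categories through the concordance.

    Every item must have an entry in ``splits`` (single-child splits express
    plain 1:1 mappings).  Mass and energy are conserved exactly: category
    totals equal item totals in both kg and kcal.

    Returns a DataFrame indexed by COICOP category with columns
    ``kg_per_capita_yr`` and ``kcal_per_capita_yr``.
    """
    items = list(items)
    unmapped = [it.fbs_code for it in items if it.fbs_code not in splits]
    if unmapped:
        raise KeyError(f"FBS items without a CPC/COICOP mapping: {unmapped}")
    kg: dict[str, float] = {}
    kcal: dict[str, float] = {}
    for item in items:
        for category, share in split_shares(splits[item.fbs_code]).items():
            kg[category] = kg.get(category, 0.0) + item.kg_per_capita_yr * share
            kcal[category] = kcal.get(category, 0.0) + item.kcal_per_capita_yr * share
    return pd.DataFrame(
        {"kg_per_capita_yr": kg, "kcal_per_capita_yr": kcal}
    ).fillna(0.0)


def footprint_intensity(
    ff_per_capita: float,
    supply_kg: float,
    supply_kcal: float,
    key: str = "diet",
) -> IntensityRecord:
    """Diet intensity: FF divided by annual supply in kg and in 1,000 kcal."""
    if supply_kg <= 0 or supply_kcal <= 0:
        raise ValueError(
            f"{key}: supply must be > 0 (got {supply_kg} kg, {supply_kcal} kcal)"
        )
    if ff_per_capita < 0:
        raise ValueError(f"{key}: footprint must be >= 0")
    return IntensityRecord(
        key=key,
        gha_per_kg=ff_per_capita / supply_kg,
        gha_per_1000kcal=ff_per_capita / (supply_kcal / 1000.0),
    )


# ---------------------------------------------------------------------------
# CSV readers

def read_fbs_supply(path) -> dict[str, list[FoodSupplyItem]]:
    """Read fbs_supply.csv (fbs_code, kg_per_capita_yr, kcal_per_capita_yr[, region])."""
    df = pd.read_csv(path)
    required = {"fbs_code", "kg_per_capita_yr", "kcal_per_capita_yr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "region" not in df.columns:
        df = df.assign(region="")
    out: dict[str, list[FoodSupplyItem]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.region), []).append(
            FoodSupplyItem(r.fbs_code, float(r.kg_per_capita_yr), float(r.kcal_per_capita_yr))
        )
    return out


def read_cpc_splits(path) -> dict[str, CpcSplit]:
    """Read cpc_splits.csv (fbs_code, cpc_code, coicop_category, world_import_qty)."""
    df = pd.read_csv(path)
    required = {"fbs_code", "cpc_code", "coicop_category", "world_import_qty"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, CpcSplit] = {}
    for code, grp in df.groupby("fbs_code", sort=False):
        children = tuple(
            CpcChild(str(r.cpc_code), str(r.coicop_category), float(r.world_import_qty))
            for r in grp.itertuples()
        )
        out[str(code)] = CpcSplit(str(code), children)
    return out
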