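"""Seeded synthetic worlds with known ground truth.

The real 141-region, 65-sector MRIO database behind published footprint
accounts is licensed, so the pipeline is exercised on small synthetic
economies that are valid by construction:

* gross output is heavy-tailed (log-normal), transactions are sparse
  (Bernoulli mask x gamma magnitudes) with within-region blocks denser than
  cross-region blocks (``trade_openness`` controls the off-diagonal mass);
* each column of Z is scaled so the technical-coefficient column sum stays
  below ``rho_max`` — for a nonnegative matrix the spectral radius is
  bounded by the largest column sum, so rho(A) <= rho_max holds by
  construction;
* Z is then shrunk so every row's residual ``x - Z.1`` is positive and
  becomes final demand, split over consuming regions by a Dirichlet draw
  biased toward the domestic column (more so at low openness);
* extensions are built from drawn per-region production footprints through
  the standard allocation scheme, and sector-to-COICOP concordance rows are
  Dirichlet draws tilted toward food categories for food-producing sectors.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_accounts import LAND_TYPES
from .consumption_pipeline import CoicopConcordance
from .extension_builder import ExtensionTable, SectorAllocationScheme, build_extension
from .mrio_model import MRIOWorld

FOOD_CATEGORIES: tuple[str, ...] = (
    "bread and cereals",
    "meat",
    "fish and seafood",
    "milk, cheese and eggs",
    "vegetables",
)
NONFOOD_CATEGORIES: tuple[str, ...] = (
    "housing and utilities",
    "personal transportation",
    "goods and services n.e.c.",
)

#: Equivalence factors by land type (gha per hectare), loosely world-like.
_EQF = {
    "cropland": 2.5,
    "grazing": 0.45,
    "forest": 1.3,
    "fishing": 0.35,
    "builtup": 2.5,
}


class InfeasibleWorldError(RuntimeError):
    """The generator could not produce a balanced world for this spec."""


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world."""

    n_regions: int = 3
    n_sectors: int = 6
    seed: int = 0
    rho_max: float = 0.6
    trade_openness: float = 0.3
    eu_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_sectors < 1:
            raise ValueError("need at least one region and one sector")
        if not 0.0 < self.rho_max < 1.0:
            raise ValueError(f"rho_max must be in (0, 1), got {self.rho_max}")
        if not 0.0 <= self.trade_openness <= 1.0:
            raise ValueError(f"trade_openness must be in [0, 1], got {self.trade_openness}")

    @property
    def region_names(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]

    @property
    def sector_names(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_sectors)]

    def resolved_eu_members(self) -> tuple[str, ...]:
        """Explicit members if given, else the first half of the regions."""
        if self.eu_members:
            return tuple(self.eu_members)
        return tuple(self.region_names[: max(1, self.n_regions // 2)])


@dataclass
class SyntheticWorld:
    """A world bundle: economy, extensions, concordance, biocapacity.

    Also the in-memory form of a bundle loaded from disk, in which case the
    optional tables may be absent (None) and ``scheme`` is not recoverable.
    """

    spec: WorldSpec
    world: MRIOWorld
    efp: pd.DataFrame | None
    scheme: SectorAllocationScheme | None
    extension: ExtensionTable | None
    concordance: CoicopConcordance | None
    biocapacity: pd.DataFrame | None
    eu_members: tuple[str, ...] = ()


@dataclass(frozen=True)
class FoodTables:
    """Synthetic food-balance, concordance-split and waste tables."""

    supply: dict[str, list]  # region -> list[FoodSupplyItem]
    splits: dict[str, object]  # fbs_code -> CpcSplit
    waste: list  # list[WasteRecord]


def _default_scheme(spec: WorldSpec, rng: np.random.Generator) -> SectorAllocationScheme:
    R, S = spec.n_regions, spec.n_sectors
    emission = rng.dirichlet(np.full(S, 1.5), size=R)
    value_added = rng.dirichlet(np.full(S, 1.5), size=R)
    if S < 4:
        # Too few sectors for disjoint land-type groups: every group covers
        # all sectors and splits by output share.
        allsec = list(range(S))
        return SectorAllocationScheme(
            cropland_sectors=allsec,
            grazing_sectors=allsec,
            forest_sector=0,
            fishing_sector=min(1, S - 1),
            emission_share=emission,
            value_added_share=value_added,
            strict=False,
        )
    n_crop = max(1, round(0.25 * S))
    n_graz = max(1, round(0.12 * S))
    while n_crop + n_graz + 2 > S:
        if n_crop > 1:
            n_crop -= 1
        else:
            n_graz -= 1
    crop = list(range(n_crop))
    graz = list(range(n_crop, n_crop + n_graz))
    return SectorAllocationScheme(
        cropland_sectors=crop,
        grazing_sectors=graz,
        forest_sector=n_crop + n_graz,
        fishing_sector=n_crop + n_graz + 1,
        emission_share=emission,
        value_added_share=value_added,
    )


def _draw_economy(spec: WorldSpec, rng: np.random.Generator) -> MRIOWorld:
    R, S = spec.n_regions, spec.n_sectors
    n = R * S
    openness = spec.trade_openness
    x = rng.lognormal(mean=np.log(1000.0), sigma=0.5, size=n)

    region_of = np.repeat(np.arange(R), S)
    same_region = region_of[:, None] == region_of[None, :]
    p_link = np.where(same_region, 0.7, 0.15 + 0.6 * openness)
    magnitude_scale = np.where(same_region, 1.0, 0.15 + 0.85 * openness)
    W = (rng.random((n, n)) < p_link) * rng.gamma(2.0, 1.0, size=(n, n)) * magnitude_scale

    # Column-sum bound: A's column j sums to beta_j < rho_max, hence
    # rho(A) <= max column sum < rho_max for the nonnegative A.
    beta = rng.uniform(0.15, 0.95 * spec.rho_max, size=n)
    colsum = W.sum(axis=0)
    Z = np.where(colsum > 0, W / np.where(colsum > 0, colsum, 1.0), 0.0) * beta * x

    rowsum = Z.sum(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.where(rowsum > 0, x / np.where(rowsum > 0, rowsum, 1.0), np.inf)
    shrink = min(1.0, 0.85 * float(ratios.min()))
    Z *= shrink
    resid = x - Z.sum(axis=1)
    if np.any(resid <= 0):
        raise InfeasibleWorldError("residual final demand non-positive after rescaling")

    alpha = np.where(
        np.arange(R)[None, :] == region_of[:, None],
        1.0 + 5.0 * (1.0 - openness),
        0.5 + 2.0 * openness,
    )
    shares = np.vstack([rng.dirichlet(a) for a in alpha])
    D = resid[:, None] * shares

    populations = np.round(rng.lognormal(np.log(1e7), 0.6, size=R))
    return MRIOWorld(
        regions=spec.region_names,
        sectors=spec.sector_names,
        Z=Z,
        x=x,
        D=D,
        populations=populations,
    )


def _draw_efp(spec: WorldSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for region in spec.region_names:
        for lt in LAND_TYPES:
            rows.append({"region": region, "land_type": lt, "gha": rng.gamma(2.0, 150.0)})
    return pd.DataFrame(rows)


def _draw_concordance(
    spec: WorldSpec,
    scheme: SectorAllocationScheme,
    labels: list[str],
    rng: np.random.Generator,
) -> CoicopConcordance:
    categories = list(FOOD_CATEGORIES) + list(NONFOOD_CATEGORIES)
    n_food, n_cat = len(FOOD_CATEGORIES), len(categories)
    food_sectors = set(scheme.cropland_sectors) | set(scheme.grazing_sectors) | {
        scheme.fishing_sector
    }
    rows = np.empty((len(labels), n_cat))
    S = spec.n_sectors
    for i in range(len(labels)):
        alpha = np.full(n_cat, 0.4)
        if (i % S) in food_sectors:
            alpha[:n_food] = 4.0
        else:
            alpha[n_food:] = 4.0
        rows[i] = rng.dirichlet(alpha)
    shares = pd.DataFrame(rows, index=labels, columns=categories)
    return CoicopConcordance(shares=shares, food_categories=frozenset(FOOD_CATEGORIES))


def _draw_biocapacity(spec: WorldSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for region in spec.region_names:
        for lt, eqf in _EQF.items():
            rows.append(
                {
                    "region": region,
                    "product_id": f"{lt}-area",
                    "land_type": lt,
                    "A_N": rng.gamma(2.0, 5e5),
                    "YF_N": rng.lognormal(0.0, 0.25),
                    "EQF": eqf,
                }
            )
    return pd.DataFrame(rows)


def generate_world(spec: WorldSpec, max_retries: int = 5) -> SyntheticWorld:
    """Generate a full synthetic world bundle, deterministic given the seed."""
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            world = _draw_economy(spec, rng)
        except InfeasibleWorldError as err:  # pragma: no cover - defensive
            last_err = err
            continue
        scheme = _default_scheme(spec, rng)
        efp = _draw_efp(spec, rng)
        extension = build_extension(efp, scheme, world)
        concordance = _draw_concordance(spec, scheme, world.labels, rng)
        bc = _draw_biocapacity(spec, rng)
        return SyntheticWorld(
            spec=spec,
            world=world,
            efp=efp,
            scheme=scheme,
            extension=extension,
            concordance=concordance,
            biocapacity=bc,
            eu_members=spec.resolved_eu_members(),
        )
    raise InfeasibleWorldError(  # pragma: no cover - defensive
        f"could not balance a world for {spec} after {max_retries} attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# Food tables

_FBS_CATALOG: tuple[tuple[str, str, float, float, float], ...] = (
    # (fbs_code, default COICOP category, kg scale, kcal/kg low, kcal/kg high)
    ("#2511 wheat and products", "bread and cereals", 90.0, 2600.0, 3400.0),
    ("#2805 rice and products", "bread and cereals", 25.0, 3400.0, 3700.0),
    ("#2731 bovine meat", "meat", 13.0, 1800.0, 2800.0),
    ("#2733 pig meat", "meat", 30.0, 2200.0, 3200.0),
    ("#2734 poultry meat", "meat", 24.0, 1400.0, 2000.0),
    ("#2761 freshwater fish", "fish and seafood", 6.0, 900.0, 1400.0),
    ("#2764 marine fish, other", "fish and seafood", 10.0, 800.0, 1300.0),
    ("#2848 milk, excluding butter", "milk, cheese and eggs", 220.0, 500.0, 700.0),
    ("#2949 eggs", "milk, cheese and eggs", 12.0, 1300.0, 1500.0),
    ("#2601 tomatoes and products", "vegetables", 30.0, 200.0, 800.0),
    ("#2605 vegetables, other", "vegetables", 80.0, 250.0, 500.0),
    ("#2617 apples and products", "fruit", 20.0, 400.0, 600.0),
    ("#2563 olive oil", "plant-based oils and fats", 8.0, 8500.0, 9000.0),
    ("#2542 sugar and sweeteners", "sugar and confectionery", 32.0, 3600.0, 4000.0),
    ("#2655 wine", "alcoholic beverages", 20.0, 700.0, 900.0),
)

#: The multi-derivative FBS item and its CPC children (the "tomatoes" pattern):
#: derived products of one FBS category landing in different COICOP categories.
_TOMATO_CHILDREN = (
    ("01235 tomatoes", "vegetables"),
    ("21321 tomato juice", "non-alcoholic beverages"),
    ("21399 paste of tomatoes", "vegetables"),
    ("21393 peeled tomatoes", "vegetables"),
)


def generate_food_tables(spec: WorldSpec) -> FoodTables:
    """Synthetic FBS supply, CPC splits and waste records for every region.

    Per region, 8-15 FBS items with kg and kcal supply (energy densities in
    the 200-9,000 kcal/kg range); at least one item splits over several CPC
    children; household waste dominates retail waste.
    """
    from .diet_metrics import CpcChild, CpcSplit, FoodSupplyItem
    from .scenarios import WasteRecord

    rng = np.random.default_rng([spec.seed, 104729])
    n_items = int(rng.integers(8, 16))
    catalog = list(_FBS_CATALOG)
    # Always keep the multi-derivative tomatoes item; sample the rest.
    others = [c for c in catalog if not c[0].startswith("#2601")]
    keep_idx = rng.choice(len(others), size=n_items - 1, replace=False)
    chosen = [catalog[9]] + [others[i] for i in sorted(keep_idx)]

    splits: dict[str, CpcSplit] = {}
    for code, category, _, _, _ in chosen:
        if code.startswith("#2601"):
            children = tuple(
                CpcChild(cpc, cat, float(rng.gamma(2.0, 50.0)))
                for cpc, cat in _TOMATO_CHILDREN
            )
        else:
            children = (CpcChild(f"cpc-{code[1:6]}", category, 1.0),)
        splits[code] = CpcSplit(code, children)

    supply: dict[str, list[FoodSupplyItem]] = {}
    for region in spec.region_names:
        items = []
        for code, _, kg_scale, kcal_lo, kcal_hi in chosen:
            kg = float(rng.gamma(4.0, kg_scale / 4.0))
            density = float(rng.uniform(kcal_lo, kcal_hi))
            items.append(FoodSupplyItem(code, kg, kg * density))
        supply[region] = items

    waste = [
        WasteRecord(
            region=region,
            household_kg=float(rng.uniform(40.0, 90.0)),
            food_service_kg=float(rng.uniform(10.0, 35.0)),
            retail_kg=float(rng.uniform(5.0, 20.0)),
            population=float(np.round(rng.lognormal(np.log(1e7), 0.6))),
        )
        for region in spec.region_names
    ]
    return FoodTables(supply=supply, splits=splits, waste=waste)


# ---------------------------------------------------------------------------
# Planted truth

_PT_CATEGORIES = (
    "bread and cereals",
    "meat",
    "housing and utilities",
    "personal transportation",
)
_PT_FOOD = frozenset(_PT_CATEGORIES[:2])


@dataclass
class PlantedTruth:
    """An autarkic world whose per-category footprints have a closed form."""

    bundle: SyntheticWorld
    expected_category_gha: pd.DataFrame  # regions x categories
    expected_ff_per_capita: pd.Series  # per region

    @property
    def world(self) -> MRIOWorld:
        return self.bundle.world


def planted_truth_world(seed: int = 0, n_regions: int = 3) -> PlantedTruth:
    """Build a block-diagonal (autarkic) world with analytically known FF.

    Each region has four single-chain sectors mapped 1:1 to COICOP
    categories (two food, two non-food); A is diagonal, so sector i's
    footprint for its own region's demand is ``sum_l F[l, i] * d_i / (1 - a_i)``
    in closed form.
    """
    rng = np.random.default_rng([seed, 424243])
    S = len(_PT_CATEGORIES)
    spec = WorldSpec(n_regions=n_regions, n_sectors=S, seed=seed, trade_openness=0.0)
    R = spec.n_regions
    n = R * S

    a = rng.uniform(0.1, 0.5, size=n)
    x = rng.uniform(500.0, 2000.0, size=n)
    Z = np.diag(a * x)
    resid = x - a * x
    region_of = np.repeat(np.arange(R), S)
    D = np.zeros((n, R))
    D[np.arange(n), region_of] = resid
    populations = np.round(rng.lognormal(np.log(1e6), 0.3, size=R))
    world = MRIOWorld(spec.region_names, list(_PT_CATEGORIES), Z, x, D, populations)

    E = rng.gamma(2.0, 20.0, size=(len(LAND_TYPES), n))
    F = E / x[np.newaxis, :]
    extension = ExtensionTable(E=E, F=F)

    shares = pd.DataFrame(
        np.tile(np.eye(S), (R, 1)), index=world.labels, columns=list(_PT_CATEGORIES)
    )
    concordance = CoicopConcordance(shares=shares, food_categories=_PT_FOOD)

    efp = pd.DataFrame(
        [
            {
                "region": region,
                "land_type": lt,
                "gha": float(E[li, ri * S : (ri + 1) * S].sum()),
            }
            for ri, region in enumerate(spec.region_names)
            for li, lt in enumerate(LAND_TYPES)
        ]
    )

    # Closed form: sector i serves only its own region, so its contribution
    # is sum_l F[l, i] * d_i / (1 - a_i).
    per_sector = F.sum(axis=0) * resid / (1.0 - a)
    expected = pd.DataFrame(
        per_sector.reshape(R, S),
        index=spec.region_names,
        columns=list(_PT_CATEGORIES),
    )
    ff = expected[list(_PT_FOOD)].sum(axis=1) / populations
    ff.name = "ff_per_capita"

    scheme = _default_scheme(spec, np.random.default_rng([seed, 7]))
    bundle = SyntheticWorld(
        spec=spec,
        world=world,
        efp=efp,
        scheme=scheme,
        extension=extension,
        concordance=concordance,
        biocapacity=_draw_biocapacity(spec, rng),
        eu_members=spec.resolved_eu_members(),
    )
    return PlantedTruth(
        bundle=bundle, expected_category_gha=expected, expected_ff_per_capita=ff
    )
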