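"""Product-level ecological footprint and biocapacity accounts.

The ecological footprint (EF) of a product is the bioproductive area, in
global hectares (gha), appropriated by harvesting it (or by emitting CO2,
for the carbon component)::

    EF = P / Y_W * EQF

where ``P`` is the physical quantity harvested (tonnes, or t CO2), ``Y_W``
the world-average yield (t/ha, or the world carbon-uptake capacity in
t CO2/ha), and ``EQF`` the equivalence factor converting a land type's
hectares to world-average hectares.  Carbon is treated identically to
biomass products: the same formula with sequestration capacity as yield.

The consumption footprint follows the trade balance

    EF_C = EF_P + EF_I - EF_E

(production plus imports minus exports), while biocapacity (BC), the supply
side of the eco-balance, is

    BC = sum_i A_N,i * YF_N,i * EQF_i

over national bioproductive areas ``A_N`` scaled by national yield factors
``YF_N`` and equivalence factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: The six land types of footprint accounting, in canonical order.
LAND_TYPES: tuple[str, ...] = (
    "cropland",
    "grazing",
    "forest",
    "fishing",
    "builtup",
    "carbon",
)

#: 1 global hectare expressed in global square metres (display conversion).
GM2_PER_GHA = 10_000.0


class InvalidFactorError(ValueError):
    """A yield, equivalence or yield factor is non-positive."""


def _check_land_type(land_type: str) -> None:
    if land_type not in LAND_TYPES:
        raise ValueError(
            f"unknown land type {land_type!r}; expected one of {LAND_TYPES}"
        )


@dataclass(frozen=True)
class ProductFlow:
    """A physical product (or CO2) flow with its conversion factors.

    Parameters
    ----------
    product_id
        Free-form product label.
    P
        Quantity harvested per year (tonnes), or t CO2 emitted for carbon.
    Y_W
        World-average yield (t/ha/yr), or world carbon-uptake capacity
        (t CO2/ha/yr) for carbon.
    EQF
        Equivalence factor (gha per world-average hectare).
    land_type
        One of :data:`LAND_TYPES`.
    """

    product_id: str
    P: float
    Y_W: float
    EQF: float
    land_type: str

    def __post_init__(self) -> None:
        _check_land_type(self.land_type)
        if self.P < 0:
            raise ValueError(f"{self.product_id}: P must be >= 0, got {self.P}")
        if self.Y_W <= 0 or self.EQF <= 0:
            raise InvalidFactorError(
                f"{self.product_id}: Y_W and EQF must be > 0 "
                f"(got Y_W={self.Y_W}, EQF={self.EQF})"
            )


@dataclass(frozen=True)
class BiocapacityRecord:
    """National bioproductive area with yield and equivalence factors."""

    product_id: str
    A_N: float
    YF_N: float
    EQF: float
    land_type: str

    def __post_init__(self) -> None:
        _check_land_type(self.land_type)
        if self.A_N < 0:
            raise ValueError(f"{self.product_id}: A_N must be >= 0, got {self.A_N}")
        if self.YF_N <= 0 or self.EQF <= 0:
            raise InvalidFactorError(
                f"{self.product_id}: YF_N and EQF must be > 0 "
                f"(got YF_N={self.YF_N}, EQF={self.EQF})"
            )


def ef_product(flow: ProductFlow) -> float:
    """Footprint of a single product flow, in gha: ``P / Y_W * EQF``."""
    return flow.P / flow.Y_W * flow.EQF


def ef_consumption_balance(ef_p: float, ef_i: float, ef_e: float) -> float:
    """Trade-balance consumption footprint ``EF_P + EF_I - EF_E`` (gha).

    A negative result is possible for re-export-heavy (entrepot) economies;
    it is preserved, with a warning, rather than clamped so that the
    accounting identity holds across regions.
    """
    for name, v in (("ef_p", ef_p), ("ef_i", ef_i), ("ef_e", ef_e)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    ef_c = ef_p + ef_i - ef_e
    if ef_c < 0:
        warnings.warn(
            f"negative consumption footprint ({ef_c:.6g} gha): exports exceed "
            "production plus imports (re-export-heavy economy?)",
            stacklevel=2,
        )
    return ef_c


def biocapacity(records: Iterable[BiocapacityRecord]) -> pd.Series:
    """Biocapacity in gha by land type, ``sum A_N * YF_N * EQF``.

    Returns a Series over all six land types (zeros where no records) whose
    ``.sum()`` is the total BC. Additive over record lists by construction.
    """
    totals = dict.fromkeys(LAND_TYPES, 0.0)
    for rec in records:
        totals[rec.land_type] += rec.A_N * rec.YF_N * rec.EQF
    return pd.Series(totals, name="bc_gha")


@dataclass
class FootprintAccount:
    """Per-region footprint components by land type, checked against EF_C = EF_P + EF_I - EF_E."""

    region: str
    ef_production: Mapping[str, float]
    ef_imports: Mapping[str, float]
    ef_exports: Mapping[str, float]
    ef_consumption: Mapping[str, float] = field(default_factory=dict)
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.ef_consumption:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.ef_consumption = {
                    lt: ef_consumption_balance(
                        self.ef_production.get(lt, 0.0),
                        self.ef_imports.get(lt, 0.0),
                        self.ef_exports.get(lt, 0.0),
                    )
                    for lt in LAND_TYPES
                }
        for lt in LAND_TYPES:
            lhs = self.ef_consumption.get(lt, 0.0)
            rhs = (
                self.ef_production.get(lt, 0.0)
                + self.ef_imports.get(lt, 0.0)
                - self.ef_exports.get(lt, 0.0)
            )
            scale = max(abs(lhs), abs(rhs), 1.0)
            if abs(lhs - rhs) > self.tol * scale:
                raise ValueError(
                    f"{self.region}/{lt}: EF_C={lhs} violates EF_P+EF_I-EF_E={rhs}"
                )

    @property
    def total_consumption(self) -> float:
        return float(sum(self.ef_consumption.get(lt, 0.0) for lt in LAND_TYPES))


@dataclass(frozen=True)
class EcoBalance:
    """Per-capita footprint vs biocapacity; negative balance is an ecological deficit."""

    region: str
    ef_per_capita: float
    bc_per_capita: float

    @property
    def balance(self) -> float:
        return self.bc_per_capita - self.ef_per_capita

    @property
    def deficit(self) -> bool:
        return self.balance < 0


def eco_balance(
    ef_per_capita: float, bc_per_capita: float, region: str = ""
) -> EcoBalance:
    """Eco-balance of a region: BC minus EF, both in gha/person."""
    if ef_per_capita < 0 or bc_per_capita < 0:
        raise ValueError("per-capita EF and BC must be >= 0")
    return EcoBalance(region, ef_per_capita, bc_per_capita)


# ---------------------------------------------------------------------------
# CSV readers (UTF-8, comma separated, "." decimal, header required)

def read_product_flows(path) -> list[ProductFlow]:
    """Read product_flows.csv (product_id, land_type, P, Y_W, EQF)."""
    df = pd.read_csv(path)
    required = {"product_id", "land_type", "P", "Y_W", "EQF"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ProductFlow(r.product_id, float(r.P), float(r.Y_W), float(r.EQF), r.land_type)
        for r in df.itertuples()
    ]


def read_biocapacity(path) -> dict[str, list[BiocapacityRecord]]:
    """Read biocapacity.csv (product_id, land_type, A_N, YF_N, EQF[, region]).

    Returns records grouped by region; a file without a region column maps
    everything to the empty-string region.
    """
    df = pd.read_csv(path)
    required = {"product_id", "land_type", "A_N", "YF_N", "EQF"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "region" not in df.columns:
        df = df.assign(region="")
    out: dict[str, list[BiocapacityRecord]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.region), []).append(
            BiocapacityRecord(
                r.product_id, float(r.A_N), float(r.YF_N), float(r.EQF), r.land_type
            )
        )
    return out
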