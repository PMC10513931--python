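"""Multi-regional input-output (MRIO) algebra.

A world of R regions with S sectors each is stored region-major: row
``r * S + s`` is sector ``s`` of region ``r``.  From the transaction matrix
``Z`` (currency/yr) and gross output ``x``, the technical coefficient matrix
is ``A = Z @ diag(x)^-1``; the economy is productive iff the spectral radius
rho(A) < 1, in which case total requirements are given by the Leontief
inverse ``L = (I - A)^-1``.  The consumption footprint of a final-demand
vector d under an environmental-extension intensity matrix F (gha per
currency) is ``F @ L @ d``, resolved here by producing sector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_BALANCE_TOL = 1e-8


class NonProductiveEconomyError(ValueError):
    """Spectral radius of the coefficient matrix is >= 1."""


class WorldValidationError(ValueError):
    """The MRIO world violates shape, sign or row-balance constraints."""


@dataclass
class MRIOWorld:
    """A multi-regional economy: transactions, output, final demand.

    Attributes
    ----------
    regions
        Ordered region labels (length R).
    sectors
        Ordered sector labels, identical across regions (length S).
    Z
        Inter-industry transactions, RS x RS, currency/yr.
    x
        Gross output, length RS, currency/yr.
    D
        Final demand, RS x R; column r is region r's demand vector.
    populations
        Persons per region, length R.
    """

    regions: list[str]
    sectors: list[str]
    Z: np.ndarray
    x: np.ndarray
    D: np.ndarray
    populations: np.ndarray
    tol: float = DEFAULT_BALANCE_TOL

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def n_rows(self) -> int:
        return self.n_regions * self.n_sectors

    @property
    def labels(self) -> list[str]:
        """Region-major ``"REG:sector"`` row labels."""
        return [f"{r}:{s}" for r in self.regions for s in self.sectors]

    @property
    def region_of_row(self) -> np.ndarray:
        """Region index of each of the RS rows."""
        return np.repeat(np.arange(self.n_regions), self.n_sectors)

    def region_slice(self, region: str) -> slice:
        r = self.regions.index(region)
        return slice(r * self.n_sectors, (r + 1) * self.n_sectors)

    def validate(self) -> None:
        n = self.n_rows
        if self.Z.shape != (n, n):
            raise WorldValidationError(f"Z must be {n}x{n}, got {self.Z.shape}")
        if self.x.shape != (n,):
            raise WorldValidationError(f"x must have length {n}, got {self.x.shape}")
        if self.D.shape != (n, self.n_regions):
            raise WorldValidationError(
                f"D must be {n}x{self.n_regions}, got {self.D.shape}"
            )
        if self.populations.shape != (self.n_regions,):
            raise WorldValidationError("populations must have one entry per region")
        if np.any(self.x < 0):
            raise WorldValidationError("gross output x must be nonnegative")
        if np.any(self.Z < 0):
            raise WorldValidationError("transactions Z must be nonnegative")
        if np.any(self.D < 0):
            warnings.warn(
                "negative final-demand entries present (inventory drawdowns?); "
                "kept as-is",
                stacklevel=2,
            )
        resid = self.x - self.Z.sum(axis=1) - self.D.sum(axis=1)
        scale = np.maximum(np.abs(self.x), 1.0)
        bad = np.abs(resid) > self.tol * scale
        if np.any(bad):
            labels = [self.labels[i] for i in np.flatnonzero(bad)[:5]]
            raise WorldValidationError(
                f"row balance x = Z.1 + D.1 violated at {labels} "
                f"(max residual {np.abs(resid).max():.3g})"
            )


@dataclass
class CoefficientMatrix:
    """Technical coefficients A (dimensionless) with validated rho(A) < 1."""

    A: np.ndarray
    spectral_radius: float = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if np.any(self.A < 0):
            raise ValueError("A must be nonnegative")
        # Zero columns contribute only zero eigenvalues, so rho of the full
        # matrix equals rho of the nonzero-output submatrix.
        self.spectral_radius = float(np.max(np.abs(np.linalg.eigvals(self.A)))) if self.A.size else 0.0
        if self.spectral_radius >= 1.0:
            raise NonProductiveEconomyError(
                f"economy is not productive: spectral radius rho(A) = "
                f"{self.spectral_radius:.6g} >= 1"
            )


def technical_coefficients(world: MRIOWorld) -> CoefficientMatrix:
    """A_ij = Z_ij / x_j, with all-zero columns for zero-output sectors."""
    x = world.x
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(x[np.newaxis, :] > 0, world.Z / x[np.newaxis, :], 0.0)
    return CoefficientMatrix(A)


def leontief_inverse(A: CoefficientMatrix | np.ndarray) -> np.ndarray:
    """Total-requirements matrix L = (I - A)^-1.

    Solved column-wise against the identity rather than by explicit matrix
    inversion; equals the mathematical inverse to ~1e-10 for productive A.
    """
    mat = A.A if isinstance(A, CoefficientMatrix) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    eye = np.eye(n)
    try:
        return np.linalg.solve(eye - mat, eye)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded by rho check
        raise NonProductiveEconomyError(f"(I - A) is singular: {err}") from err


def total_requirements_footprint(
    F: np.ndarray, A: CoefficientMatrix | np.ndarray, demand: np.ndarray
) -> np.ndarray:
    """Consumption footprint by land type x producing sector (gha).

    Entry ``[l, j]`` is ``F[l, j] * (L @ demand)[j]``: the footprint exerted
    in producing sector j, directly and through its supply chain, to serve
    the demand vector.  Row sums give the scalar footprint F @ L @ d per
    land type.
    """
    F = np.asarray(F, dtype=float)
    demand = np.asarray(demand, dtype=float)
    mat = A.A if isinstance(A, CoefficientMatrix) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    if F.ndim != 2 or F.shape[1] != n:
        raise ValueError(f"F must be (n_land, {n}), got {F.shape}")
    if demand.shape != (n,):
        raise ValueError(f"demand must have length {n}, got {demand.shape}")
    total_output = np.linalg.solve(np.eye(n) - mat, demand)  # L @ d
    return F * total_output[np.newaxis, :]
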