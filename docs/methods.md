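# Methods

## Accounting model

The package implements consumption-based ecological footprint (EF)
accounting in two layers.

**Product layer.** The footprint of a product flow is `P / Y_W × EQF`:
physical quantity over world-average yield, converted to global hectares
(gha) by the land type's equivalence factor. The carbon component is the
same formula with tonnes of CO₂ as the quantity and the world-average
carbon-uptake capacity per hectare as the yield; carbon is therefore
treated identically to biomass products throughout. The consumption
footprint by the physical-trade route is `EF_C = EF_P + EF_I − EF_E`. A
negative `EF_C` (exports embedding more area than production plus
imports, as can happen for entrepôt economies) is reported with a warning
but never clamped, so that the identity — and hence global conservation,
Σ EF_C = Σ EF_P over a closed world — survives aggregation. The import
and export terms are inputs at this layer; computing them from bilateral
physical trade is out of scope, which is precisely what the MRIO layer
replaces.

**MRIO layer.** An R-region, S-sector world is stored region-major
(RS rows). From transactions `Z` and gross output `x`, technical
coefficients are `A = Z diag(x)⁻¹` with zero-output columns set to zero
(those columns contribute only zero eigenvalues, so the spectral-radius
check on the full matrix equals the check on the productive submatrix).
The economy must satisfy ρ(A) < 1; otherwise a non-productive-economy
error names the offending radius. The Leontief total-requirements matrix
`(I − A)⁻¹` is obtained by a linear solve against identity columns, not
an explicit inverse; results agree with the mathematical inverse to
about 1e-10. The consumption footprint of demand vector `d` is
`F (I − A)⁻¹ d` per land type, where `F` is the extension intensity
matrix (gha per currency unit of sector output).

**Attribution.** The scalar `F L d` is resolved two ways: by *producer*
(`F ∘ (L d)`, where the area is appropriated — the basis of the
domestic / intra-group / extra-group origin decomposition) and by
*demanded sector* (`(F L) ∘ d`, which final purchase drives it — the
basis of the COICOP recategorization). Both marginals of the full tensor
`F_l[i]·L[i,j]·d[j]` sum to the same total, and the tidy output of the
pipeline uses the tensor so category, land type and origin are resolved
jointly. Supply-chain (indirect) components — feed cropland inside meat,
carbon of transport — are carried automatically by the Leontief
structure; no extra bookkeeping is applied.

**Extensions.** Per region, cropland and grazing production footprints
are split over their sector groups; forest and fishing go to single
sectors; carbon is split by each sector's share of regional CO₂
emissions; built-up land by value-added share. Within-group weights
default to each member's share of gross output inside the group and can
be overridden — the group-internal split is a genuinely open choice, and
output-proportionality is the neutral default. The allocation conserves
the input EF_P per region × land type to 1e-9 relative (tested).
The scheme supports any sector count; worlds with fewer sectors than
land-type groups (the 1×1 scalar world used for closed-form checks)
relax the group-disjointness constraint explicitly via `strict=False`.

**COICOP and the food footprint.** A sector-to-category concordance with
rows summing to 1 redistributes demand-side footprints into consumption
categories, conserving total gha. The food footprint (FF) is the sum of
the flagged food categories divided by population. The pipeline treats
each region's full final-demand column as household demand; inputs that
distinguish demand components can restrict to a household sub-column
upstream. Per-capita values use the population from the input table
as-is, with no interpolation.

## Diet metrics

FBS-style supply tables carry kg and kcal per capita per item; energy
densities are taken from the table, never recomputed. Multi-derivative
items are split to COICOP categories through CPC children in proportion
to world import quantities; the production-side import mix is used as a
proxy for the consumption mix, deliberately without correction. The
splitting is scale-invariant and conserves mass and energy exactly.
Intensities are FF / supply in gha/kg and gha per 1,000 kcal; the latter
is also displayed in global m² (×10,000) per the field's convention. The
concordance module takes a single pre-averaged supply table; multi-year
averaging happens upstream.

## Scenarios

Iso-caloric substitution operates on the per-1,000-kcal intensity basis:
replaced kcal = fraction × intake × energy density, and the FF change is
replaced kcal/1000 × (intensity difference). A mass-basis substitution is
intentionally not offered: substituting "equivalent kcal provision" is
the meaningful dietary counterfactual. Waste elimination uses the
proportional average-intensity model — the FF reduction equals the
waste's share of supplied food mass — which is exact when the wasted
food's intensity mix matches the diet's average. Waste streams
(household, food service, retail) aggregate across regions by
population weighting. Scenario functions return new values and never
mutate baselines.

## Synthetic worlds

The generator emulates the structure of a licensed production MRIO at
desk scale, not its magnitudes:

* gross output is log-normal (median 1000 currency units, σ = 0.5),
  giving the heavy right tail of real sector sizes;
* transactions are a Bernoulli mask × gamma magnitudes, with
  within-region blocks denser (link probability 0.7) than cross-region
  blocks (0.15–0.75, rising with `trade_openness`, which also scales
  cross-border magnitudes);
* each column of Z is scaled so its coefficient column-sum is a uniform
  draw below `rho_max` (default 0.6). For a nonnegative matrix the
  spectral radius is bounded by the largest column sum, so ρ(A) ≤
  `rho_max` holds by construction rather than by rejection;
* Z is then shrunk so every row's residual `x − Z·1` stays positive and
  becomes final demand, split over consuming regions by a Dirichlet draw
  biased toward the domestic column (strongly at low openness);
* production footprints per region × land type are gamma draws routed
  through the standard allocation scheme; concordance rows are Dirichlet
  draws tilted toward food categories for crop/grazing/fishing sectors;
* food tables draw 8–15 FBS items from a fixed catalog with plausible
  energy-density bands (200–9,000 kcal/kg), always including one
  multi-derivative item split across CPC children; household waste
  ranges dominate retail.

All draws flow from one seeded generator, so identical seeds give
identical worlds. What the synthetic world does **not** emulate: real
price levels, the 65-sector/141-region resolution of production
databases, sectorally structured technology (A is statistically
homogeneous within blocks), or empirically calibrated footprint
magnitudes. Green tests therefore demonstrate the correctness of the
accounting algebra and its conservation laws, not agreement with any
real region's published footprint.

The planted-truth world is the degenerate case used for exact recovery:
autarkic regions, diagonal A, one sector per COICOP category, so each
sector's footprint has the closed form `Σ_l F[l,i] · d_i / (1 − a_i)`
and per-category footprints are known analytically.

## Numerical choices

* Identity and conservation checks use 1e-9 relative tolerance
  (floating-point sums over many cells); Leontief-vs-series checks use
  1e-8 with a 300-term truncated Neumann series as the independent
  oracle (ρ ≤ 0.8 makes the truncation error ≪ 1e-8).
* Negative final-demand entries load with a warning (inventory
  drawdowns occur in real tables); negative transactions are rejected.
* Stranded footprints (E > 0 in a zero-output sector) warn and produce
  zero intensity, since there is no output to carry them.
* Bundle CSVs are written with `%.17g` and read with round-trip float
  parsing, so write→load is bit-identical and re-running the pipeline on
  the same inputs reproduces output files byte for byte.
* Test and validation problem sizes are R ≤ 5, S ≤ 8 — ample to exercise
  every code path (multi-region trade, group allocation, concordance
  mixing) while keeping the whole suite in seconds.

## Known limitations

* Only CO₂ enters the carbon component; other greenhouse gases are
  outside the ecological-footprint method by design.
* The origin decomposition takes an explicit member list for the
  "rest of group" share; it does not decide what the group should be.
* The waste model is proportional: it cannot distinguish wasting
  high-intensity from low-intensity foods.
* Scenario arithmetic is static — no rebound, price or substitution
  feedbacks beyond the specified swap.
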