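# Methods

This note documents the model implemented by `deserisk`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Indicator system and orientation

The canonical configuration (`deserisk/data/indicator_system.csv`) carries
19 indicators: 7 hazard (precipitation, evaporation, sand-driving wind
days, temperature, vegetation coverage index, cultivation rate, grazing
capacity), 4 exposure (grassland area, farmland area, population density,
economic density), 4 vulnerability (soil physical–chemical properties of
grassland and farmland, agricultural population ratio, primary-industry GDP
ratio) and 4 restorability (area of returning farmland to forests,
population output, number of students, sand-control inputs ratio). Each row
stores the four grade boundaries in ascending numeric order, the
(level-1-lower, level-5-upper) envelope, the combined weight, and a
semantic orientation flag: *risk-increasing* (more of it, more risk) or
*risk-decreasing* (precipitation, vegetation coverage, and all
restorability indicators, since more restorability means less risk).

The five-grade membership functions need a *direction*, and it is derived
from the orientation per factor: grades measure the indicator's **factor**
index, and restorability enters the composite index through its complement
(1 − R). A restorability indicator that reduces risk therefore grades
*upward* in restorability (more students → higher restorability grade →
higher R → lower risk), while a risk-decreasing hazard indicator such as
precipitation grades *downward* (more rain → lower hazard grade). This
resolution (direction = orientation flipped within the restorability
factor) is what makes the composite index monotone: non-decreasing in H, E,
V and non-increasing in R, which the test suite checks on 10⁴ random factor
tuples.

## Trapezoidal grade partition

For ascending boundaries b₁ < b₂ < b₃ < b₄ (increasing direction) the eight
split points are

    a1− = b1 − |b1|/4        a1+ = (3b1 + b2)/4
    a2− = (b1 + 3b2)/4       a2+ = (3b2 + b3)/4
    a3− = (b2 + 3b3)/4       a3+ = (3b3 + b4)/4
    a4− = (b3 + 3b4)/4       a4+ = b4 + |b4|/4

and the decreasing direction is the exact mirror (descending boundaries,
outer extensions by |b|/4 on both ends). Two repairs of the tabulated
formula set are deliberate:

- the increasing-type outer split is sometimes quoted as a4+ = b4 + b1/4;
  by symmetry with the decreasing case it is implemented as b4 + |b4|/4
  (the quoted variant survives behind `derive_split_points(...,
  literal_outer=True)`);
- the decreasing-type outer split 3b₄/4 equals b4 − |b4|/4 only for
  non-negative b4; the absolute-value form is used so mirror duality
  (decreasing membership at x ≡ increasing membership at −x with negated
  boundaries, grades reversed) holds identically. Every canonical boundary
  is non-negative, so both repairs change nothing on the shipped
  configuration.

Membership is evaluated through cumulative ramp transitions t₀ = 1 ≥ t₁ ≥ …
≥ t₄ ≥ t₅ = 0 with v_g = t_{g−1} − t_g, which telescopes to an exact
partition of unity for every finite input (checked to 1e−12 over 10⁴ random
values per indicator). Plateau edges are closed; a zero-width outer ramp
(|b| = 0) degenerates to a crisp step, the limiting trapezoid. Non-finite
inputs propagate as masked cells, never exceptions.

## Weighting

Three modes are supported. `table` (default) uses the configured combined
weights verbatim, renormalized within each factor — the anchored choice,
since the pairwise matrices and entropy inputs behind them are not
available. `entropy` computes objective weights from the layers themselves:
each layer is min–max normalized (direction from its membership direction),
cells are the evaluation units, subsampled (seeded) to ≤10⁴ jointly valid
cells, and w_j ∝ 1 − e_j with e_j the column's Shannon entropy of
proportional shares (0·ln 0 := 0; constant columns get weight 0).
`combined` multiplies the table weights (as the subjective side) with the
entropy weights and renormalizes — the product-form combination rule. AHP
is implemented for users who do have pairwise matrices: principal
eigenvector weights with the standard random-index consistency ratio,
flagged at CR ≥ 0.1.

A caveat the tests document: the claim "duplicating an evaluation unit
preserves entropy-weight ordering" holds only when the dispersion hierarchy
is well separated; duplication shifts column entropies non-uniformly and
can swap nearly-tied weights.

## Optimal segmentation

`optimal_segmentation` is an O(k·n²) dynamic program over contiguous
partitions of a sorted sample minimizing total within-class sum of squared
deviations, the classical ordered-clustering criterion. Ties are broken
toward the smallest split index, so output is deterministic. Reported
boundaries are midpoints between adjacent class-edge values, matching the
half-open (lo, hi] interval convention of the grading standards so observed
points are never ambiguous. The DP is verified against exhaustive
enumeration of all contiguous partitions for n ≤ 12, k ≤ 4 (100 random
instances). The shipped DDRI grading boundaries (0.29, 0.47, 0.63, 0.78)
are treated as fixture constants of the model: the sample that generated
them is not available to re-derive them.

## Composite index

Factor indices are defuzzified with class-midpoint scores (0.1 … 0.9) — the
original rule for turning the fuzzy vector into the scalar the index needs
is unstated, and midpoints are the neutral choice. Aggregation is the
weighted geometric mean H^Wh E^We V^Wv (1−R)^Wr: it keeps the index in
[0, 1], annihilates when any driving factor vanishes, and reduces to the
identity when all inputs equal c with R = 1 − c (the factor weights sum
to 1). The literal weighted product (H·Wh)(E·We)(V·Wv)((1−R)·Wr) is
available via `aggregation="product"` for sensitivity comparison only; its
scale is not commensurate with the grading standards. Grading uses
right-closed intervals, so 0.29 grades very low and 0.47 grades low.

## Synthetic data

The generator emulates the study conditions: a 100×100 grid of 1 km cells,
13 contiguous regions, 19 indicator fields, and a loss layer coupled to
risk. Fields are moving-average-smoothed Gaussian white noise (kernel 5
cells by default) affinely rescaled to span each indicator's envelope
exactly — enough spatial autocorrelation to exercise zonal statistics
without a full geostatistical simulator. Regions are a seeded Voronoi
partition (convex, hence contiguous, cells). Losses are
`slope · DDRI + N(0, sd)` floored at 0, with defaults slope 100 loss-units
per unit risk and sd 5; at those defaults the regional loss–risk R² lands
around 0.86, the regime reported for real regional loss validation, and at
sd = 0 it is exactly 1. The floor at 0 is a mild nonlinearity; validation
tolerances allow for it. All three generators are bit-deterministic given
the seed (per-indicator child seeds are spawned from one seed sequence).

What passing synthetic tests shows: the arithmetic of every stage, the
partition/monotonicity invariants, and that the validation machinery
recovers a known coupling at realistic noise. What it does not show:
that the indicator system or weights are right for any real landscape —
real fields have anisotropy, trends, cross-correlation between indicators
and irregular administrative geometry that the generator deliberately omits.

## Problem sizes and numerics

Default experiment sizes — 100×100 cells, 13 regions, 10⁴-value property
sweeps, 100-instance segmentation cross-checks, 100-replicate slope
recovery on 30×30 grids — were chosen so the whole suite runs in seconds
while keeping sampling error far below the asserted tolerances. Partition
of unity is asserted at 1e−12 (exact telescoping), OLS against summation
formulas at 1e−10, DP against enumeration at 1e−10. Degenerate inputs
(constant layers, zero x-variance, fewer than five distinct values, k > n)
raise typed errors rather than producing NaNs; masked cells propagate
through every stage and are excluded from all statistics.

## Known limitations

- Real-raster ingestion is limited to the ESRI ASCII grid dialect; no CRS
  handling or reprojection.
- The fuzzy composition is the weighted-sum operator; max–min and other
  compositions are out of scope.
- The grade-to-scalar step (defuzzification) is a declared convention, not
  a reconstruction of the unstated original rule.
- Grid-level loss correlation (`validation.gridwise_fit`) is exploratory
  only; the designed analysis is regional.
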