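# Methods

This note documents the models, conventions and numerical choices behind
`tlstree`, in the order data flows through the pipeline.

## Synthetic stems and stands

The generator emulates the stem forms of very large coastal conifers as a
minimal analytically-integrable family. The trunk surface is

    r(z, θ) = r₀(z) · B(z) · (1 + Σₖ aₖ cos(kθ + φₖ)),
    r₀(z)   = R · (1 − z/H)^t,
    B(z)    = 1 + g · (1 − z/h_b)   for z < h_b, else 1,

with base radius `R`, taper exponent `t` (0 = cylinder, 1 = cone; redwoods
sit near 0.7–1.0), buttress gain `g` and buttress height `h_b` (basal flare
vanishing linearly at `h_b`, default 3.5 m — hence the above-buttress DTB
slab at 4–4.5 m), and fluting harmonics `k ≥ 2` with Σ|aₖ| < 1. Distinct
harmonics are orthogonal over the circle, so the cross-section area has the
closed form `A(z) = π (r₀ B)² (1 + ½Σaₖ²)`; trunk volume ground truth is a
trapezoid quadrature of `A(z)` at Δz = 1 cm (halving Δz moves the result by
< 0.05%), and the 1.3 m equivalent-area diameter `dbh_true = 2√(A(1.3)/π)`
is exact. Branches are straight cylinders in whorls (exact volume and
lateral-area formulas); no reiterations or epicormics — enough to exercise
the trunk/branch decomposition, not a crown model. Surface-area truth omits
the axial slope factor √(1+(dr/dz)²), which is < 0.5% for these tall stems,
matching the lateral-only cylinder convention below.

Sampling: rings of points at the global spacing, with two refinements that
mirror a tripod scanner in a plot. First, the bands around the two
measurement slabs (1.0–1.7 m and 3.8–4.8 m) are sampled at ~3.3 cm when the
whole-tree budget dictates a coarser grid — the lower trunk is at close
range, so its real density is far above the whole-tree average. Second,
occlusion removes one contiguous azimuth sector (fraction of 2π) only
*above* 5 m: multiple co-registered scan positions see the lower trunk from
all sides, while shadowing grows with height. Without this, a coarse or
occluded breast-height ring cannot close and the concave hull degenerates —
which is the correct behaviour for genuinely incomplete sections, and is
reported as such rather than patched. Range noise is Gaussian, applied
radially (σ default 5 mm, the ranging-accuracy class of survey-grade
scanners). Everything is reproducible from the spec's seed; ground truth is
analytic and never touches the sampled points.

Defaults for the study cohort (`cohort_specs`): three 0.25 ha plots of
26/36/83 trees plus one separate ~88 m, DBH 3.39 m giant (146 trees);
DBH lognormal in [0.15, 2.2] m; height H = 50·DBH^0.46 with 8% lognormal
scatter (placing the giant near 88 m); 2–3 fluting harmonics totalling
4–14% amplitude; buttress gain 0.15–0.45; branch whorls every ~3 m from
0.3 H giving ~10–20% branch volume fraction. These are fixed study
conditions, not tuning knobs.

What the generator does *not* emulate: leaves/needles, bark microrelief,
terrain, beam divergence and footprint physics, multi-return artefacts,
reiterated trunks. Passing tests therefore demonstrate correctness of the
geometric estimators under clean stem-like geometry with realistic noise
and occlusion — not performance on arbitrary field clouds.

## Stem dimensions

Slabs are half-open `[z_lo, z_hi)` measured above the *lowest point* of the
cloud (never a ground model), and collapsed to 2D by dropping z. A slab
with < 20 points is an error; the failed quantity is reported missing while
the others are still returned.

**Circle fit (DBH, DTB).** Taubin's algebraic fit initialises a
Levenberg–Marquardt refinement of the geometric objective Σ(dᵢ − r)²; the
reported RMSE is √(mean (dᵢ − r)²) of the final fit. The RMSE is used
downstream as the 1-σ uncertainty of the diameter — a deliberately
conservative convention (it is per-point scatter, dominated by non-circular
bark and flutes, not the standard error of r̂).

**Alpha shape (fDBH).** Delaunay triangles with circumradius < 1/α are
kept (α in m⁻¹, default 4.0, so larger α = tighter; this matches the
widely-used Python alphashape toolbox convention — alpha conventions differ
across libraries, so this is stated prominently). A TLS bark section is a
hollow ring of points, so the *region enclosed by the complex boundary* is
taken: interior holes are filled (equivalent to polygonizing the boundary
edges, which is what the alphashape toolbox does), multiple disjoint
components keep the largest by filled area, and a largest component below
20% of the convex-hull area raises a degenerate-alpha error. fDBH =
2√(area/π) exactly. The alpha-shape fit RMSE has no canonical definition;
here it is the RMS distance to the boundary polyline over input points
within 5 cm of it — a documented convention used as the fDBH uncertainty.

## Cylinder model (QSM)

A deliberately simple estimator with the standard QSM output contract.
Skeleton: symmetric k-NN graph (k = 10; disconnection is an error carrying
the orphan fraction), Dijkstra geodesic distance from a base source band
(points within max(2.5 × median NN spacing, 5 cm) of the lowest point —
seeding from the whole base ring keeps shells horizontal on thick trunks),
shells of width `patch_size`, connected clusters within each shell as
segments, parent = the previous-shell cluster with the most graph edges
into the segment. The trunk is the root-to-tip path of maximum cumulative
point count (ties: more own points, then lower segment id — radii are not
known at skeleton time).

Cylinders: axis from the segment chain; the segment's points are projected
onto the plane normal to the axis and the same Taubin + geometric circle
fit gives centre (re-anchoring the axis) and radius, so partial arcs from
occlusion are handled correctly; wild fits (radius > 2.5 × the projected
extent, the short-arc failure mode) fall back to the mean point-to-axis
distance, and segments with < 10 points inherit the parent radius. Axial
extents of consecutive segments on a limb share their boundary at the
midpoint of the overlapping projections, so chain cylinders tile the stem
exactly — this is what brings a noise-free cylinder to within 0.1% of
πr²H. Branch-root cylinders extend back to the parent cylinder's surface
(their first shell merges into the trunk cluster at the junction). Volume
is Σπr²L (trunk + branch = total exactly, by construction); surface area
is lateral only, Σ2πrL — end caps would double-count at joints.

Ensembles re-run the fit over a patch-size grid (default {0.3, 0.5, 0.8} m)
× 3 seeded jitters (95% point subsample, k ∈ {8, 10, 12}); the mean ± sample
SD (n−1) of total volume is the per-tree TLS volume and its uncertainty.
Failed runs are logged and excluded; an empty ensemble is an error.

## Allometric models and biomass

Three forms cover the bank: `log_log` (ln M = β₀ + β₁ ln D, with a
correction factor ≥ 1 for back-transformation bias), `power_product`
(M = a·ΠXᵢ^bᵢ) and `volume_then_density` (V = a·ΠXᵢ^bᵢ, M = ρV). All
coefficients live in a versioned YAML config — the code validates presence
and never embeds values. Units: meters internally; a model may declare
centimeter predictors and kilogram response (the US generalised equations
do). Masses are metric tons (Mg) throughout. Wood density defaults to
380 kg m⁻³, the basic-density class published for coastal redwood; the
five species-specific forms share it with the TLS conversion, so the
TLS-vs-species-specific comparison is a pure volume comparison.

The bank's two generalised models (Jenkins cedar/larch, Chojnacky
Cupressaceae 0.30–0.39) carry their published coefficients. The five
species-specific redwood models are **synthetic stand-ins** (so labelled in
the config): their original coefficient tables are not distributed here, so
each stated functional form — DBH,H volume; D²H volume; DTB,fDBH volume;
DTB,H volume; DBH-only log-log with correction factor — was calibrated once
on the generator's analytic stem family (`scripts/calibrate_standin_models.py`)
and frozen. They exercise the pipeline and reproduce the *structure* of a
TLS-vs-allometry comparison; they do not predict real redwood biomass.

Uncertainty propagation is Monte-Carlo (default 1000 seeded draws):
each predictor ~ Normal(value, fit RMSE) truncated at zero; the AGB sample
SD is reported. The first-order delta method (σ_M ≈ M·β₁·σ_D/D for log-log)
is kept as an independent cross-check in the tests and agrees within 20%
whenever RMSE/value < 5%. H carries no fit RMSE and is held fixed.

New allometries (`fit_power_law`): nonlinear least squares on
y = a·ΠXᵢ^bᵢ, initialised by log-space linear regression, refined with
absolute (`weighting="none"`) or relative residuals; reported
`rmse_percent = 100·RMSE/mean(response)`. The pipeline's in-study refits
use absolute weighting so the in-sample optimum is guaranteed no worse
than any fixed coefficients of the same form. Coefficient standard errors
come from the final-iteration Jacobian; the tests cross-check them with a
parametric bootstrap.

## Comparison statistics

Model-vs-TLS regressions are ordinary least squares of model AGB (y) on
TLS AGB (x) in arithmetic tons — TLS is the reference; near-unit slopes
with small intercepts make arithmetic space the natural choice, and a
log-space option exists for sensitivity. CV% = 100·RMSE/mean(reference).
The with/without-largest-tree pair quantifies the leverage of a single
giant on an allometric calibration. AGBD = ΣAGB/area exactly; its standard
error combines per-tree SDs in quadrature (independent-tree assumption —
QSM ensemble SD for TLS, Monte-Carlo SD for allometric estimates).

## Problem sizes and determinism

Cloud budgets are chosen so the full test suite runs in a couple of minutes
and the acceptance script in about one: cohort trees target ~12 k points
(the giant ~48 k), closed-form solids ~20 k, the standalone giant-tree
ensemble ~120 k points × 9 runs. Cylinder-model accuracy at these budgets
is ~0.1% (cylinder), ~2% (cone, stair-casing), ~5% (branched trees), ~7%
(giant tree ensemble). All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical clouds,
ensembles and Monte-Carlo draws.

## Known limitations

No lean/tilt correction (slabs are horizontal); bark vs wood volume is not
distinguished; branch structure beyond first-order whorls is not modelled;
the alpha-shape fit RMSE and the diameter-uncertainty conventions are
package conventions, not community standards; stand-in allometric
coefficients are synthetic (above); plot AGBD ignores within-plot spatial
structure; crown volume and foliage quantities are out of scope.
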