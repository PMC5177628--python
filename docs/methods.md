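# Methods

## Gradient arithmetic

Gradient media are treated as ideal binary mixtures: volumes are additive
and the mixture density is the volume-weighted mean of the component
densities. No excess-volume or temperature correction is applied; the
constants shipped are n-heptane 0.68 g cm⁻³ and tetrachlorethylene
1.60 g cm⁻³, the pair that makes a 0.484:1 heptane:TCE mixture come out at
1.300 g cm⁻³. Both are configurable (`SolventComponent`), since literature
values for TCE at 20–25 °C run slightly higher (~1.62). Plans track the
carried volume cumulatively across steps and each step is verified by
recomputing the mixture density (tolerance 1e-9). Volumes are rounded to
3 decimals (microlitres) only in the pipetting table; internal arithmetic
is full precision.

## Percent normalization and detection masks

Raw marker activities and metabolite peak areas are normalized per analyte
to percent of their detected sum (tolerance on the 100 % invariant: 1e-9).
Missing metabolite values (empty cells) are "not detected": they carry no
percent and their fractions are excluded from pair building. Marker
profiles must be complete. An analyte with no positive detected value has
no distribution and is reported as skipped, never silently zeroed. The
toolkit accepts already blank-corrected activities; no correction of its
own is applied.

## Hit-counting assignment

For a metabolite detected in k ≥ 2 fractions, slopes (plain
percentage-point differences; see below) are built over all C(k, 2)
detected pairs and compared to the marker slopes on the same pairs.
Per pair, Ψ(comp) = |Δmet − Δcomp|; the configuration then controls:

* **bounds** — default (5, 7.5, 10) percentage points. Per bound *b*, every
  compartment with Ψ − min(Ψ) < *b* earns one hit; the grading lets small
  slope differences count more than large ones. Comparison is strict by
  default (`strict_inequality`), so a boundary-equal excess does not hit.
* **scheme** — under the default `bound-loop` the arg-min compartment's
  excess is 0, below every bound, so it earns exactly `len(bounds)` hits
  and a full three-way tie yields 33.3/33.3/33.3 (the analytically forced
  outcome when all marker profiles coincide). The alternative
  `min-plus-bounds` awards one extra hit to the first arg-min compartment
  (compartment order breaks ties) on top of the bound hits; it is kept for
  sensitivity analysis because on full ties it skews to 40/30/30.
* **slope convention** — slopes are percent differences, not divided by
  density spacing: the distances subtract slopes of identically indexed
  pairs, so any common denominator cancels. A density-normalized variant
  (`density_normalized_slopes`) is provided for gradients with uneven
  spacing where users prefer it.

A metabolite detected in exactly **one** fraction is assigned by the
marker maximum in that fraction: the top compartment receives
`single_fraction_hit_weight` hits (default 3 = `len(bounds)`, so the
special case weighs like one unanimous pair). Ties at the maximum follow
`tie_policy`: `all-pass` (default) gives every tied compartment the full
weight, `split` divides it; both normalize to the same distribution.

Hit totals are normalized to percent per replicate; replicates are
aggregated as arithmetic mean and sample SD (n−1; a single replicate
reports SD 0). Absolute levels use the product of means,
level = rel%/100 · whole-tissue mean, with SD propagated as
level·√((SDrel/rel)² + (SDwhole/whole)²) — per-replicate pairing of
fractionated and non-fractionated samples is not assumed, since the two
measurements come from different extracts.

## Statistics

Condition effects per (metabolite, compartment) are tested by one-way
ANOVA (scipy); with more than two conditions Tukey's HSD (statsmodels)
supplies pairwise p-values. Stars follow the usual strict thresholds
(* p<0.05, ** p<0.01, *** p<0.001) and arrows the sign of the last-minus-
first condition mean difference. No correction across metabolites is
applied. Degenerate all-constant, all-equal groups report p = 1.

For clustering, variables are scaled row-wise to z-scores with the sample
SD (n−1, matching the replicate convention; configurable); constant rows
are dropped with a warning. Agglomeration uses Euclidean distances with
average linkage by default (single/complete/ward selectable — the linkage
choice is a genuinely open design point and is therefore exposed rather
than fixed). Leaf order follows scipy's tie-breaking and is documented as
order-dependent only up to ties. An optional 1.5×IQR outlier screen is
provided but never applied automatically.

## Synthetic experiments

The generator emulates the data a benchtop NAF run produces, not the
physics of the separation:

* **Marker shapes** — discretized Gaussian optima over the relative
  fraction axis, plastid banding light (center 0.15), cytosol intermediate
  (0.50), vacuole dense (0.85), common width 0.18; each profile sums
  to 100. The overlap is deliberate: neighbouring compartments compete on
  some fraction pairs, as real marker distributions do. Narrower widths
  and fewer fractions (e.g. f = 5, width 0.14) produce fully separated
  regimes where every inter-compartment slope pair differs by more than
  the largest bound; identical centers produce the tie regime.
* **Metabolites** — convex mixtures of the marker percent profiles with
  Dirichlet(1,1,1) ground-truth weights, scaled by a per-metabolite
  peak-area magnitude (log-uniform over 10⁴–10⁷) and perturbed by i.i.d.
  multiplicative lognormal noise with mean 1 and CV `noise_cv`
  (default 0.05, of the order of the technical error the uncertainty
  bounds absorb; no published figure exists, so the value is a documented
  stand-in exposed in the config).
* **Design** — defaults: f = 6 fractions spanning 1.20–1.55 g cm⁻³,
  3 replicates, one condition; a second condition draws independent truth
  weights. Optional missingness knocks out fractions at a configured rate
  while keeping every profile detectable. All randomness flows from one
  master seed through `SeedSequence.spawn`, so outputs are bit-reproducible.

What passing synthetic tests shows — and does not. The generator's mixture
model matches the assignment's own premise (fractions as compartment
mixtures), so recovery results validate the algorithm's logic, seeding and
normalization, not its robustness to real-data pathologies: marker enzymes
measured with noise, cross-contaminating particle populations, saturated
peaks or compartment counts beyond three are outside the simulated space.
At the default study conditions (200 metabolites, 5 % noise, 3 replicates,
f = 6) the dominant compartment of metabolites with max weight ≥ 0.6 is
recovered in ≥ 80 % of cases (empirically ~100 %); the threshold lives in
the test configuration.

## Numerical conventions and edge cases

* Fractions are 1-based in all I/O, fraction 1 the lightest (last)
  supernatant; internal arrays keep that order 0-based.
* Percent invariants are enforced at 1e-9; presentation rounding (one
  decimal, e.g. 33.3) happens only in output tables.
* Hit counts are exact small floats (integers under `all-pass`; `split`
  can produce halves/thirds), so distributions are exact ratios before
  rounding.
* Problem sizes in the test suite (≤ 500 random instances, 200 synthetic
  metabolites) were chosen as comfortable desk-scale validation runs;
  the algorithms are O(f²) per metabolite and scale far beyond that.

## Known limitations

Three compartments with complete marker profiles are assumed; organelles
that band together (mitochondria, peroxisomes) are not resolved — the
marker set is extensible in configuration but no additional marker
constants ship. No least-squares deconvolution estimator is offered; the
hit-counting procedure is the estimator. Gradient planning covers a single
binary solvent pair and ignores temperature dependence of densities.
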