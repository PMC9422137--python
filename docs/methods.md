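# Methods

## The question and the model

Linear anthropogenic features — pasture fences and roads, separately or in
tandem — alter where ungulates go and how they move. The package quantifies
two distinct responses for a partially migratory population:

- **Crossing effect** (fine scale): does an animal select against *steps*
  that cross a feature? Covariates are counts of crossings of each feature
  class along a 4-h movement step.
- **Proximity effect** (broad scale): does an animal position itself away
  from features? Covariates are distances (m) from a location to the nearest
  feature of each class.

Features are partitioned into four mutually exclusive configuration classes:
pasture fence not associated with a road (`FENCE`), road with no fence
(`RNF`), road fenced on one side (`R1F`), and road fenced on both sides
(`R2F`). Treating configurations as separate covariates, rather than fence ×
road interactions, is the point: crossing a road flanked by two fences is a
different behavioral problem from crossing two pasture fences and an open
road, even though an interaction code would conflate them.

Both effects are estimated with matched used–available conditional logistic
regression. Each used location (or step) is matched with `k = 5` available
alternatives in a stratum, and the likelihood conditions on one used
candidate per stratum:

    l(β) = Σ_s [ β'x_used(s) − log Σ_{j∈s} exp(β'x_j) ]

With exactly one case per stratum this equals the stratified Cox partial
likelihood, which is how such models are conventionally fit; we maximize the
softmax form directly by Newton iterations with analytic gradient and
Hessian (convergence at gradient max-norm < 1e-8 or relative log-likelihood
change < 1e-12; starting value β = 0; step-halving keeps the likelihood
non-decreasing). Standard errors come from the inverse observed information;
`model.cluster_robust_se` additionally provides animal-clustered sandwich
SEs, since strata within one individual share a trajectory and are serially
dependent.

Candidate models are all 2⁵ subsets of the covariate blocks {FENCE, RNF,
R1F, R2F, LANDCOVER} (the empty set is the null model), ranked by AIC with
Akaike weights; models with ΔAIC < 2 of the best form the competing set. The
selected model is refit on Gelman-standardized covariates — centered at the
mean and divided by twice the SD, computed jointly over used and available
candidates — so continuous coefficients are comparable with indicator ones.
Effects are reported as relative selection strength: log-RSS = β'(x₁ − x₂),
RSS = exp(log-RSS). Crossing contrasts compare one crossing against none
with the other features held at 0 and land cover at NATIVE (so a one-unit
contrast is exactly exp(β)); proximity curves sweep one distance over
[0, 1000] m against its mean, other covariates at their means.

## Data preparation rules

- **Fix schedule.** Relocations arrive on a nominal 4-h schedule (tolerance
  ±15 min, configurable; GPS schedules jitter). Relocations with no
  conforming neighbor either 4 h before or after are isolated on the
  schedule and dropped — this filter is idempotent. Crossing-scale strata
  additionally require a contiguous previous step (the turning-angle
  reference), so crossing sample sizes are always at or below proximity
  sample sizes.
- **Inclusion.** Animals enter an analysis with at least 500 in-study-area
  relocations (inclusive); animals may leave the area, but only in-area
  relocations count and enter strata.
- **Availability.** Crossing scale: 5 step lengths and 5 turning angles are
  drawn independently, with replacement, from the *same animal's* observed
  steps (per-individual empirical kernels avoid circularity across
  individuals); candidate headings are referenced to the previous used
  step's heading. A parametric gamma/von Mises kernel is available as an
  alternative (`choiceset.ParametricKernel`), used for sensitivity checks
  and in simulation studies where the generating kernel is known. Proximity
  scale: 5 points drawn area-uniformly (r = R√u) in a 6746-m disc around
  each used point — the radius is the 90th percentile of 4-day displacement
  distances previously established for this population.
- **Crossing counts.** Transversal intersections between the step segment
  and each feature polyline, each crossing counted (a zigzag across one
  fence counts every pass). Conventions for measure-zero contact: an
  endpoint touching a line counts once; a collinear overlap stretch counts
  once. Counts are capped at the nearest-rank 98th percentile of the pooled
  used+available counts, per tactic and per class — the caps keep rare
  extreme counts from driving the fit toward separation. A class whose
  pooled counts are all zero gets cap 0 and is flagged constant; models
  containing it cannot be estimated and are excluded from Akaike weights
  with a warning.
- **Distances** are point-to-nearest-polyline, capped at 1000 m (the range
  over which this species has previously shown responses); an empty layer
  yields the cap, with a warning.
- **Land cover** is reclassified to NATIVE (native prairie, shrub, wetland),
  ANNUAL_CROP, PERENNIAL, and OTHER (tree covers, exposed, developed,
  water), evaluated at candidate endpoints, with ANNUAL_CROP the reference
  category; off-map points fall back to OTHER with a counted warning.
- **Collinearity screen.** Pairwise Pearson correlations over the model
  covariates; pairs with |r| strictly above 0.7 are warned about, never
  auto-dropped; zero-variance covariates are reported as undefined.
- Tactics (migrant / resident — the tactic is an input label, not inferred
  here) are analyzed in fully independent runs: separate kernels, caps,
  screens, model sets, and standardizations.

## Building the configuration layers

Roads are buffered by their right-of-way half-width — 40 m for paved
(divided or undivided) roads, 20 m for gravel/county roads — and partitioned
into subsegments of at most 50 m (finer than the narrowest buffer, so class
boundaries land near fence endpoints). For each subsegment, each side is
declared fenced when the fences clipped to that side's buffer rectangle
cover at least 50% of the subsegment's extent when projected onto its axis.
The coverage rule (rather than a nearest-point test) is what makes a fence
that merely *crosses* the road contribute nothing: a crossing fence has
essentially zero along-track extent, while a roadside fence covers the
subsegment. Sides fenced: 0 → RNF, 1 → R1F, 2 → R2F; runs of equal class are
merged; fence stretches inside any road buffer are consumed by the road's
classification and removed from the FENCE layer, so one physical fence is
never double-counted. The side test is orientation-independent and conserves
road length exactly (subsegments are substrings of the original
centerlines). Subsegments are treated via their chords, exact for straight
roads and a close approximation at 50-m splits of curved ones.

Coordinates are assumed planar metric (projected); there is no geodesic
computation, and a layer whose coordinates fall in lon/lat degree ranges is
rejected.

## The synthetic study system

`synth` generates everything the pipeline consumes, so every stage is
testable with no external data.

**Landscape.** A rectangular extent (default 30 × 30 km) with a grid of
pasture fences (spacing 2.8 km), a sparser road grid (spacing 2.5 km; a mix
of paved and gravel classes), and each road divided into ~5-km stretches
assigned no fence / one side / both sides as an exact-proportion shuffled
deck (default shares 63/23/14% of road length). The defaults put class
densities near a fenced rangeland system — FENCE ≈ 0.73, RNF ≈ 0.51,
R1F ≈ 0.18, R2F ≈ 0.11 km/km² — with pasture fences denser than all roads
combined and double-fenced roads rarest. Roadside fences are emitted as raw
fence polylines 12 m off the centerline, so the classifier can be exercised
against the generator's ground truth. Land cover is painted as 1-km square
patches (60% NATIVE, 25% ANNUAL_CROP, 10% PERENNIAL, 5% OTHER, drawn from
raw classes so the reclassification table is exercised), extending 3 km past
the extent so simulated candidates stay on-map.

**Movement.** Each animal takes 4-h steps: M = 50 candidate endpoints are
drawn from a gamma(shape 1.3, scale 600 m) step-length and von Mises(μ = 0,
κ = 0.5) turning-angle kernel around the current heading, and one is chosen
with probability ∝ exp(β'x + bias). The means (~780-m steps) are plausible
for a mobile plains ungulate on a 4-h fix and give realistic encounter rates
with even the rarest feature class. The covariates x (crossing counts per
class, endpoint land cover, optionally distances) are computed by the same
code the analysis uses — `covariates.StackedLayerIndex` — so simulator and
estimator cannot drift apart. The bias term is a weak pull toward the
current range center (default 4e-4 utility per meter): residents hold one
home range year-round; migrants dwell on a winter range, switch their center
to a summer range 12 km away at mid-track, and dwell there, producing the
two-plateau net-squared-displacement signature of migration. Default true
penalties are negative for all four classes (−2.0, −1.5, −1.2, −1.0 for
FENCE, RNF, R1F, R2F) with land-cover preferences (+0.5 NATIVE, −0.75 OTHER
vs ANNUAL_CROP); these reproduce the qualitative structure of a
fence-and-road avoiding ungulate without purporting to be estimates of any
real population. Simulation uses uncapped covariates — capping is an
estimator-side device, not a process property. Animals leaving a 2-km guard
margin are reflected (logged per animal).

**What the generator does not emulate.** No fix loss or location error, no
habitat-dependent step lengths, no mortality or collar failure, no traffic
or fence-design variation, no seasonal kernel changes. Passing tests
therefore demonstrate correctness of the machinery and estimator under the
assumed selection process, not robustness to the full messiness of field
telemetry.

## Estimator validation and its subtleties

`validation.recovery_study` runs the whole chain end-to-end against known
parameters: replicates of 10 resident animals × 1500 steps on a
balanced-exposure landscape (road stretches 40/30/30% unfenced / one side /
both sides over a 40 × 40 km arena, so the rare R2F class is identifiable),
analyzed by the standard pipeline. Two deliberate design choices deserve
explanation:

- **Availability from the generating kernel.** With the default empirical
  kernel, realized steps are selection-distorted (animals choose shorter,
  crossing-avoiding steps), so availability drawn from them under-represents
  what was truly reachable, and the crossing penalties attenuate
  appreciably — compare `crossing_summary.csv` against the true penalties in
  `sim_manifest.json` — though every sign still recovers.
  This availability bias is a well-known property of step-selection designs,
  present in any field application of the method, not an implementation
  error. The recovery study therefore draws availability from the known
  generating gamma/von Mises kernel, making the estimand equal the
  generator's β; a companion test documents that signs (not magnitudes)
  recover under the empirical kernel.
- **Finer candidate sets in the generator.** The discrete-choice simulation
  approximates the continuous redistribution kernel with an O(1/M) error;
  at the default M = 50 the residual bias is a measurable fraction of a
  standard error at 15,000 strata, so recovery replicates generate with
  M = 100, keeping approximation error well below estimation noise.

Model-selection behavior is validated on smaller replicates (6 animals × 400
steps): under the strong default effects the full model should win the AIC
ranking; under a true null — *all* selection coefficients and the range pull
zeroed, so used and available steps are exchangeable — a model without
feature terms should sit within ΔAIC < 2 of the top. Two caveats are worth
recording. First, zeroing only the feature penalties is not a null: residual
land-cover selection or range attraction leaks real, unmodeled utility into
the crossing covariates through the empirical kernel, and AIC correctly
(not spuriously) picks it up. Second, even under a perfect null, AIC admits
a model one parameter larger than the truth whenever its likelihood-ratio
statistic exceeds 4 (probability ≈ 0.05 per direction), so occasional
replicates where a feature model outranks the null by more than 2 AIC are
expected behavior of AIC, not a defect.

Wald CI coverage in the recovery study is evaluated per coefficient across
replicates (`recovery_study.csv`); model-based SEs sit slightly under the
nominal 95% — the shortfall reflects within-animal dependence and cap
truncation — and the animal-clustered sandwich SEs with a t(G−1) critical
value are reported alongside.

## Numerical choices and degenerate inputs

- Nearest-rank percentile (the ⌈p/100·n⌉-th order statistic) for caps — a
  deterministic convention for an "approximate" percentile.
- Turning angles in (−π, π], counterclockwise positive; the first step of a
  chain has no turning angle and anchors no crossing stratum.
- Separation is flagged (not silently reported) when any |β| exceeds 15
  during or after optimization; the information matrix turning singular
  (e.g., a cap-0 constant covariate) marks the fit non-converged and drops
  it from Akaike weights.
- All randomness flows through `numpy.random.Generator` seeded from the run
  configuration; per-animal streams are spawned deterministically from the
  run seed in sorted-animal order, so a full run is reproducible
  byte-for-byte from (inputs, config, seed).
- CSV track I/O writes floats at 17 significant digits and parses with
  round-trip precision, so write→read is exact.
- Problem sizes in the shipped tests and scripts (replicate counts, animals,
  steps) are chosen so the full validation battery completes comfortably on
  one CPU while leaving the statistical thresholds meaningful; the study
  designs above state the sizes used.

## Known limitations

- The conditional model treats strata as independent; only the sandwich SEs
  acknowledge within-animal dependence, and with few animals those are
  themselves noisy (hence t(G−1) critical values).
- Empirical-kernel availability attenuates coefficient magnitudes (above);
  reported magnitudes from field-style runs should be read accordingly.
- The side-coverage rule evaluates subsegment chords; roads curving sharply
  within 50 m could misattribute a side near the curve.
- Proximity-effect coefficients on simulated data are emergent (distance
  effects arise from crossing penalties piling animals against barriers),
  so no ground-truth distance β exists to recover; the proximity pipeline
  is validated for correctness and determinism, not parameter recovery.
- Land cover is static and categorical; no terrain, traffic volume, or
  fence-design covariates.
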