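# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `nicheshift`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design

The pipeline compares two climate periods — a *reference* and a *future*
period related by a uniform warming offset — and asks how the change in
modelled species distributions plays out across a network of protected
areas: species gain, loss, turnover and richness per protected area;
representativity of protected areas at three nested spatial scales; and
the change in protected land overlapping each species' range. Species are
assumed to track their suitable climate fully; colonization and dispersal
are deliberately not modelled, so future occupancy should be read as
*potential* occupancy.

## The synthetic landscape

The generator emulates the statistical structure of a northern study
system, not any particular geography.

**Grid.** Square cells in planar, unprojected coordinates; a nominal
`cell_size` of 20 km gives 400 km² cells. Row index increases southward
("latitude" = decreasing row). Cell edges are half-open so a point on a
shared edge belongs to exactly one cell. No CRS is used: geodesy is
irrelevant to the statistics, and planar geometry keeps areas exact.

**Climate.** Each variable is a linear gradient along rows (latitudinal,
e.g. temperature) or columns (longitudinal, e.g. a coastal moisture
gradient) plus iid Gaussian noise. The default panel of four —
`temp`, `gdd` (growing degree days, nearly collinear with `temp`),
`precip` (column-axis), `aridity` (weak row gradient, noise-dominated) —
is deliberately structured so the screening stage has a genuinely
redundant variable to drop and a near-orthogonal variable to keep. The
future period adds each variable's warming offset to every cell (default
+3° on `temp`, +360 on `gdd`, none on the moisture variables); the
cell-level noise field is shared between periods, i.e. the anomaly is
purely additive.

**Virtual species.** Suitability is a product over niche variables of
Gaussian (optionally skew-normal) response curves peaking at 1. Birds and
amphibians respond to `temp`; trees and other vascular plants to `temp`
and `precip`; trees additionally prefer a random subset of the categorical
soil classes (7 surface-deposit and 3 drainage classes, iid per cell),
with suitability multiplied by 0.25 off-preference. Breadths are drawn as
5–15 % of each variable's observed range and scaled by √k for k niche
variables so the joint range core keeps a comparable size across taxa
(a product of k bells otherwise shrinks the core sharply). Niche optima
are drawn between the 5th and 95th percentile of the reference climate,
extended 35 % beyond the warm end so that a realistic fraction of species
are southern "immigrants": absent (or nearly so) from the reference
landscape but gaining range under warming. Occurrence is sampled once per
cell as Bernoulli(suitability × sampling rate), independent across cells —
matching the per-cell presence/absence structure the models consume, with
no spatial autocorrelation in detection.

**Protected areas.** Axis-aligned rectangles placed uniformly inside the
extent; areas are lognormal (median 5 km², log-sd 1.2, truncated at 40×
the cap), which keeps ≥95 % of areas below the 50 km² cap while retaining
a heavy right tail of large parks. Areas may overlap. **Region
hierarchy:** provinces are contiguous row bands and regions contiguous
column bands within each province (a seeded Voronoi mode is available);
nesting — every region inside exactly one province — is enforced by
construction and checked.

**Default demo scale.** 30 × 20 cells, 60 species (20/8/12/20 by taxon),
150 protected areas, sampling rate 1, master seed 1. This is large enough
for distributional statements about the network while keeping a full run
in about a minute on one CPU; the niche-recovery experiment uses the same
600-cell grid with a 20-species cohort.

## Predictor screening

Candidates are scanned greedily in a documented priority order; a variable
is retained iff |Pearson r| with every already-retained variable is
*strictly* below the threshold (default 0.6). The default priority ranks
the biologically relevant variables (`temp`, `precip`) ahead of their
proxies (`gdd`, `aridity`), mirroring expert-led variable choice: with a
neutral (alphabetical) order, a collinear proxy can displace the causal
variable itself, and if the proxy lacks a warming offset the projected
climate signal is muted. Per-taxon retention caps default to 3 (birds,
amphibians) and 4 (trees, other plants). Greedy retention is deterministic
and guarantees feasibility, not maximum cardinality; the test suite
verifies feasibility against exhaustive subset search for ≤6 candidates.
The screen is sign-blind (|r|), and a pair at exactly the threshold is
rejected.

## Ensemble niche models

**Training sets.** For pseudo-absence taxa, eligible background cells are
those whose centre lies strictly farther than the buffer (default 2 cell
widths) from every presence centre; each of the R = 10 repetitions draws,
without replacement, exactly as many pseudo-absences as presences —
prevalence exactly 0.5. If a widespread species leaves fewer eligible
cells than presences, the buffer is halved (logged) down to 0 rather than
dropping the species; the low-level primitive instead raises, naming the
species. Trees use their recorded absences, with repetitions differing
only through the calibration split. Species with fewer than 10 presences
are skipped and logged — both standard practice and necessary for a
two-class stratified split.

**Committee.** Four families spanning linear, tree, ensemble-of-trees and
instance-based learners: ridge-regularized logistic regression on
standardized features with full quadratic terms; a depth-6 CART; 40 bagged
trees; and k-NN with k ≈ √n. The registry is pluggable
(`enm.register_family`). Each repetition fits every family on a 70/30
class-stratified calibration/evaluation split; members are scored by AUC
(rank/Mann–Whitney form, ties counting ½) on the held-out rows.

**Consensus and binarization.** The consensus is the AUC-weighted mean of
members at or above the AUC floor (default 0.7), weights normalized to
sum to 1; a species with no member above the floor is flagged
unmodellable. The binary threshold maximizes TSS (sensitivity +
specificity − 1, presence predicted where score ≥ threshold; smallest
maximizer on ties) of the *reference* consensus against the recorded
occurrence labels over all cells, and is applied unchanged to the future
projection. Calibrating on the buffered training rows instead would bias
the threshold low: the buffer deliberately removes absences near range
edges, which is desirable for fitting but distorts the absence score
distribution that TSS balances.

A property worth keeping in mind when comparing against ground truth: for
a calibrated score, the max-TSS operating point sits at the species'
**prevalence**, not at suitability 0.5. The recovery experiment therefore
binarizes the true suitability surface by the same max-TSS rule (against
the species' own sampled occurrences) before computing Jaccard overlap —
a like-for-like comparison of the estimand, rather than mixing two
different operating points. For step-function niches all definitions
coincide. The recovery cohort is 10 birds + 10 other plants with optima
inside the observed reference climate; immigrant species are excluded by
construction since an empty reference range leaves nothing to recover.

## Overlay and metrics

"Smallest polygon containing the protected area" is implemented as the
union of covering cells: species are pooled over the cells the footprint
intersects with positive area (boundary touching does not count), which
reduces exactly to the single cell's values for single-cell areas.
Protected land per cell is the area of the geometric union of all
footprints clipped to the cell — overlapping designations are counted
once — while per-protected-area distributions keep every area as its own
sampling unit, matching the dual reporting of "proportion of protected
areas" versus "proportion of protected land". Invalid polygons are
repaired (`make_valid`) or rejected with their id logged.

Impact statistics carry full floating precision internally; rounding
happens only at the reporting layer. Undefined records (refSR = 0, empty
region pool, refPR = 0) are flagged and excluded from distributions, and
counted in the run log. A protected area straddling region boundaries is
assigned to the region/province holding the majority of its covering
cells; an exact tie leaves that scale undefined for the area. Class
distributions use width-10 bins with an open top class (values ≥ 100
pooled). The Wilcoxon signed-rank comparison drops zero differences,
uses midranks for ties, reports V as the positive-rank sum, and switches
from the exact null (n ≤ 25, no ties) to the tie-corrected normal
approximation. Mean ± SD and median ± MAD (raw, unscaled) are always both
computed so the reporting layer can choose per its skew rule.

## Reproducibility

One master seed drives everything: stage seeds, per-species and
per-repetition streams are spawned from it via `numpy.random.SeedSequence`,
so a re-run with the same config is byte-identical, and stages re-run from
persisted intermediates reproduce their downstream outputs. The YAML
config round-trips unchanged and is echoed into every run report.

## What passing tests do and do not show

The synthetic landscape validates the *machinery*: bookkeeping identities
(futureSR = refSR + G − L; T ∈ [0, 100]; representativity nonincreasing
as the reference region coarsens), contracts (prevalence exactly 0.5;
zero buffer violations), oracle equivalences (AUC versus pair
enumeration; covering cells versus exhaustive scan; land union versus
stratified Monte Carlo), niche recovery under known truth, and the
directional paradox signature (northern protected areas gaining
proportionally more; significant positive richness shift). It does not
validate transfer to real data: real occurrence records are spatially
autocorrelated, observation effort is biased, climate surfaces are not
linear gradients, real niches are not products of independent bells, and
real protected areas are not rectangles. Quantities estimated on real
networks also depend on dispersal, biotic interactions and land-use
change, none of which are modelled here.

## Other limitations

* Immigrant species (no reference presences) cannot be modelled from the
  synthetic occurrence table alone and are skipped; in a real application
  their models would be trained on a larger extent and projected in.
  Consequently the exclusion path for ΔPR (refPR = 0) is exercised in unit
  tests rather than by the demo run.
* Small protected areas inherit the full values of their covering cell,
  overestimating their richness and representativity; comparisons across
  periods are unaffected, but single-area values should not be
  over-interpreted.
* The land-union accounting is exact for polygons; no geodesic correction
  is applied (planar abstraction).
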