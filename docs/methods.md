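# Methods

This note documents the models, conventions and numerical choices behind
`spescreen`, and what the synthetic-data tests do and do not demonstrate
about real LC-HRMS data.

## Consensus filtering and alignment

A feature table holds one row per detected feature per injection
(sample × replicate), with m/z in Th, retention time in minutes (0-based
run time) and a non-negative integrated area. Two reductions are applied:

**Replicate consensus.** Only features detected in *every* injection
replicate of a sample are considered real. Features are matched across
replicates within an m/z tolerance (default 5 ppm) and an RT tolerance
(default 0.2 min) — typical QTOF values; they are configuration, not
measured constants. The consensus m/z and RT are the medians over the
matched replicates (robust to one outlier replicate); the consensus area is
the arithmetic mean. The rule is applied per sample, before cross-sample
alignment.

**Alignment.** Consensus features from different samples are linked by
greedy agglomeration: features are visited in a deterministic order
(m/z, RT, −area), and each joins the nearest open group whose
intensity-weighted mean m/z and RT lie within tolerance, or opens a new
group. Greedy mz-sorted agglomeration was chosen over full graph
clustering for determinism and speed; a connected-components oracle test
guards against pathological splits at the scales used here. A group holds
at most one feature per sample: on collision the higher-area feature keeps
the slot (ties: lower RT, then lower m/z) and the displaced feature is
moved to a fresh group rather than dropped, so alignment conserves
features exactly — every input consensus feature occupies exactly one cell
of the output matrix. Visiting is restricted to blocks of the m/z-sorted
order separated by gaps wider than the tolerance, which cannot be bridged.

Raw-spectra ingestion (mzML) is deliberately a stub: peak picking and
centroiding belong to dedicated tools, and this package starts from their
exported feature tables.

## Descriptors

Retention is expressed as %ACN: the percentage of organic mobile phase at
the feature's elution time, piecewise-linearly interpolated from the
gradient program (time, %B breakpoints; %ACN ≡ %B, no dwell-volume or
dead-time correction). Gradients are mandatory configuration; the
documented default is a linear 5 → 95 %B ramp over the run, used when no
instrument program is supplied. Times beyond the last breakpoint clamp to
the final composition.

Weighted averages use each feature's mean area as weight:
`wavg = Σ(value·area)/Σ(area)`. Percentage comparisons of feature counts
round to the nearest whole percent with ties away from zero, matching how
such comparisons are conventionally printed. Empty feature sets yield
count 0, total area 0 and null averages.

## Set comparison and PCA

Exclusive intersections partition the aligned features by their exact
presence pattern across samples, so subset counts sum to the number of
features and a sample's set size is the sum over subsets containing it —
both identities are tested against powerset brute force.

The PCA preprocessing is a documented package choice (the original
processing behind such figures is rarely stated): areas are transformed by
log₁₀(x+1) — areas span orders of magnitude, and absence maps to 0, i.e.
absence is informative — and centered; unit-variance scaling is available
by flag. Samples are observations and aligned features variables. Each
component's sign is fixed so its largest-magnitude loading is positive,
making scores and plots reproducible. The pooled-QC metric is the ratio of
the mean pairwise distance among pool scores to that among sample scores
on the PC1–PC2 plane; under the null (pools drawn from the sample cloud)
it is ≈ 1, and < 1 indicates the pools cluster, i.e. instrument drift is
small relative to sample differences.

## Recovery and QC

Recovery is `100 · A_extract / (A_ref · CF)`. The accounting is
centralized here: the standard is spiked into the water sample at a known
concentration (default 100 ng/L); extraction of 1 L reconstituted in 1 mL
concentrates it by `CF = 1000`; `A_ref` is the area of the neat standard
mix per unit spike concentration, so `A_ref · CF` is the area of a fully
recovered extract under a linear detector response. Recoveries are raw by
default; a matrix-relative value is obtained by dividing by the
ultrapure-water recovery. Classification thresholds (suppression < 80 %,
enhancement > 120 %, exclusion > 1000 %) are conventional and
configurable; the outlier exclusion mirrors the practice of dropping
physically implausible values from reporting. System suitability uses the
*mean* over the reference injections (the aggregate is otherwise
unspecified in common practice) against gates of 2 ppm mass error and
3.0 s peak width.

## EEM and FRI

EEM grids default to excitation 240–450 nm every 5 nm and emission
250–600 nm every 2 nm. The inner-filter rule returns the smallest integer
dilution d with A₂₅₄/d ≤ 0.1 (strictly-above triggers dilution);
integration re-multiplies by d so volumes refer to the undiluted sample.

Regional integration uses the rectangle rule — the discrete-sum definition
of FRI — with per-node trapezoid cell widths, so node weights sum exactly
to the grid span and any tiling region set conserves the total volume to
float precision. Region boundaries follow the FRI literature: I =
ex < 250/em < 330, II = ex < 250/330 ≤ em < 380, III = ex < 250/em ≥ 380,
IV = ex ≥ 250/em < 380, V = ex ≥ 250/em ≥ 380, clipped to the measured
grid (excitation starts at 240 nm); they are configuration with these
defaults. Intervals are half-open above, closed at the global grid maxima.
MFᵢ is the inverse fractional projected area computed with the same node
weights, so a uniform spectrum gives exactly equal percent distribution.
Per-region retention is computed on raw (dilution-corrected) volumes; MF
cancels in the ratio when the region sets match. Rayleigh/Raman scatter
masking is not implemented; the Gaussian-fluorophore generator produces no
scatter ridges, and real spectra should be scatter-corrected upstream.

## Zone analysis

Zones are half-open rectangles [lo, hi) on both axes, the top interval
closed at the global maximum — the convention resolves the ambiguity of
printed "0–500 / 500–1000" bands and is tested at the boundaries (m/z 500
at the split goes to the upper band). Features outside the global bounds
(e.g. RT > 25 min under the default bands) go to a logged remainder rather
than a zone, so counts always conserve. Condition comparison reports
per-zone deltas and after/before ratios; ratios over zero are null with a
warning. No significance testing is attached to zone shifts.

## Synthetic study generator

The generator emulates the acquisition design, not the physics. Each
cartridge captures compound i with probability

p = G(rtᵢ; center, width) · affinity(chargeᵢ) · (1 − s·min(1, DOC/DOC_ref))

where G is a Gaussian retention-time window normalized to 1, affinity ∈
[0,1] per charge class (neutral/acidic/basic), s ∈ [0,1] is the
cartridge's DOM sensitivity and the DOC competition term is linear,
saturating at DOC_ref = 7.1 mg C/L (a wastewater-effluent DOC, so an
effluent-like matrix competes maximally). The captured area is
base_area · p; stochastic mode additionally retains the compound with
Bernoulli(p), while deterministic mode skips the draw so descriptor tests
are exact. This functional form is invented plumbing: it reproduces the
qualitative behaviors the indicators must detect (distinct feature sets
per capture window, DOM suppression on sensitive phases), and no claim is
made that it models sorption chemistry.

Defaults define the study conditions: pools of 1000 compounds with m/z
uniform on [50, 1000] Th and RT uniform over a 34 min run, log-uniform
base areas 10⁴–10⁷, triplicate injections with multiplicative Gaussian
noise (CV 0.15, clipped at zero), a detection limit of 10³ area units, and
nine cartridges in three designed capture-window groups (centers 7, 17,
27 min; width 6 min) whose members differ in charge affinity and DOM
sensitivity. River/effluent matrices carry DOC 1.89 / 7.1 mg C/L and two
dominant Gaussian fluorophores (fulvic-like, region III; humic-like,
region V) plus a weak protein-like component. Internal standards are
spiked at a configured true recovery and read back exactly in noise-free
mode — the round-trip identity the recovery tests rely on. Pooled-QC
samples are the mean captured profile across cartridges injected with
one-third of the sample CV.

What passing tests show — and do not. The generator has no adducts,
isotopes, chromatographic peak shapes, m/z measurement error, RT drift or
correlated matrix effects; consensus and alignment are therefore exercised
under clean id-stable coordinates plus dropout, and the tolerance-matching
code paths are validated by oracle equivalence rather than by realistic
drift. Results on real data depend on upstream peak picking and the
chosen tolerances in ways these tests cannot certify.

## Problem sizes and numerics

Default test and acceptance runs use 1000-compound pools, nine cartridges
and 43 × 176 EEM grids — sizes chosen so the full suite runs in well under
a minute while the statistical checks (uniform-mean recovery at n = 10⁴,
silhouette of designed groups > 0.5) remain stable across seeds.
Conservation identities are asserted at 10⁻⁹ relative; round trips through
text formats at 12 significant digits. Ties are broken deterministically
everywhere (documented in the alignment section); all generators are
byte-identical for a fixed seed.
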