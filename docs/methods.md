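# Methods

This note documents the models implemented in `ploidyscale`, the
assumptions behind them, the synthetic-data generators used to exercise
them, and the numerical choices that matter.

## 1. Neuron morphometry

**Geometry.** A neuron is a rooted tree read from 7-column SWC (type 1
= soma, all other structure types collapsed to "neurite").  The cell
body is modeled as a sphere of the root soma radius; multi-node somata
use the volume-equivalent radius (Σr³)^(1/3).  Each neurite edge is a
conical frustum between its end radii r₁, r₂ over the chord length l:
V = (πl/3)(r₁² + r₁r₂ + r₂²), lateral A = π(r₁+r₂)√(l² + (r₂−r₁)²).
Both formulas are verified against numerical quadrature of the solid of
revolution in the test suite (≤1e-6 relative on 1000 random edges).

**Soma-surface referencing.** Neurite path length is measured from the
soma *surface*, not the centroid: a stem edge's chord is reduced by the
root soma radius (clamped at zero) and treated as a cylinder stub of
the child radius.  This keeps neurite length independent of soma size,
which in turn makes the triploid length rescaling exact (see §5) and
avoids counting intracellular path as membrane-bearing neurite.

**Derived parameters.** Branch level is centrifugal order (stems = 1,
+1 at each bifurcation); Strahler order was rejected because per-level
length distributions are a centrifugal concept.  Mean neurite diameter
is length-weighted Σlᵢdᵢ/Σlᵢ (the unweighted per-segment mean is also
reported; the two differ little on the synthetic trees).  Maximum
radius is the 3-D Euclidean distance from the soma centroid to the
farthest node — a radial, not path, distance.  Sholl profiles count
edges crossing concentric spheres centered on the soma centroid
(default step 5 μm; an edge with endpoint distances d₁ < d₂ crosses r
when d₁ < r ≤ d₂, so tangencies are not double-counted).

**Population statistics.** Fold changes are ratios of group means with
95% percentile-bootstrap CIs resampling neurons (2000 resamples,
seeded) and Welch t-tests.  A fold is classified sub-/iso-/super-scaling
against the ploidy reference 1.5 with a configurable tolerance (default
0.1).  The length-weighted diameter distributions of two groups are
compared with a weighted Kolmogorov–Smirnov statistic whose p-value
permutes *neuron* labels (default 10,000 permutations) — segments
within a neuron are dependent, and a segment-level test would overstate
significance.  With unit weights the statistic reduces exactly to the
classical two-sample KS D (tested to 1e-12 against scipy).  The
neurite share-of-surface trend versus total volume is an OLS line with
a 95% band plus an OLS-CUSUM structural-stability test (Brownian-bridge
sup boundary); a perfect fit short-circuits to "stable".

## 2. Flow cytometry

**Gating.** Events pass FSC-W/FSC-A ≤ 1.4 (singlets), are split into
beads (bead channel ≥ 10⁴ a.u.) and non-beads, and non-beads must pass
SSC-W/SSC-A ≤ 1.4 and Hoechst ≥ 3.2×10⁴ a.u. to count as single cells.
The cutoffs are configuration values standing in for hand-drawn gates;
the defaults were set from the generator's singlet/doublet/debris
geometry (doublets carry ~1.9× width-to-area ratios; debris sits below
0.6× the diploid G1 DNA mean) so that ≥99% of labeled doublets and
debris are excluded at ≥99% cell retention.  The partition is
exhaustive, disjoint and idempotent.

**Absolute counting.** CountBright beads are supplied at 0.52×10⁵ per
50 μL and 20 μL are added per tube (20,800 beads).  Cells per brain:
N = (cells/beads) × (1/brains) × (0.52×10⁵/50) × 20.  The printed form
of this formula in the source material is typographically garbled; the
implementation uses the only reading consistent with the stated bead
stock and added volume, and the unit test anchors the worked example
(10,000 cells, 5,000 beads, 6 brains → 6,933.33).

**QC rules a–e.** a) > 5,000 bead events; b) > 10,000 single-cell
events (both strict); c) sample bead means of FSC-A and Hoechst inside
run_mean×(1±run_CV); d) sample bead CVs < 2× run CV; e) a
ploidy-matched sample from the same clutch exists in the batch.  Run
statistics pool bead events across all samples of the run.  Pass is
the strict conjunction; single-sample runs evaluate c/d against
themselves and are flagged.

**Dean–Jett–Fox deconvolution.** The Hoechst histogram (256 bins up to
the 99.9th percentile, excluding aggregates) is fit by bounded least
squares with a Gaussian G0/G1 peak, a Gaussian G2/M peak, and an
S-phase component: a second-order polynomial of underlying DNA content
between the two peak means convolved with a Gaussian whose width grows
proportionally with content (σ(u) = σ_G1·u/μ_G1, matching the
constant-CV noise of DNA dyes — the G2 peak is twice as wide as G1 on
a linear axis).  The G2 mean is initialized at 2× the G1 mode but left
free, and no synchronized-peak component is included.  The fit runs on
the G1-normalized axis, and a small ridge penalty (weight 0.1) on the
S-polynomial coefficients resolves the degeneracy in which an S spike
at the support edge mimics a peak flank; a genuine broad S has
coefficients an order of magnitude smaller and is essentially
unshrunk.  Calibration tests show per-weight bias < 0.01 and sd < 0.02
at n = 50,000 under model-matched sampling, and fraction recovery
within ±0.03 of truth labels under the full generator (whose
multiplicative lognormal noise is deliberately *not* the fit's Gaussian
peak shape).

**Marker mixtures.** PCNA (negative / diffuse / punctate) and pH3
(negative / positive) intensities are deconvolved on the log10 axis by
a k-component Gaussian mixture fit with expectation–maximization:
quantile initialization, 20 restarts with seeded jitter, tolerance
1e-8 on the log-likelihood, 500 iterations max.  Weights are the
reported population areas; assignment boundaries are posterior-equality
points.  A fit is flagged degenerate when a weight falls below 0.02 or
two means sit within two standard deviations (one population split in
half).  The implementation is cross-checked against scikit-learn's
GaussianMixture in the tests.

**Phase combination.** M = pH3-positive weight; G0 = PCNA-negative;
S = PCNA-punctate; G2 = max(0, DJF G2/M − M); G1 = the remainder,
clipped at zero and renormalized (a remainder below −0.05 raises an
inconsistency warning).  An alternative rule taking S from the DJF fit
is available (`s_from="djf"`).  The PCNA-diffuse population genuinely
spans G1 and G2, which is why G1/G2 are inferred rather than read off
a component.  Absolute counts are fractions × bead-normalized cells
per brain; CIs come from a seeded multinomial bootstrap of the
classified events (1000 resamples) — refitting all three models per
resample would cost three orders of magnitude more time for CIs that
are binomial to first order.

## 3. Ratio imaging

pERK and ERK projections (sum by default; mean available — the choice
is a flag because either convention appears in practice) are divided
pixelwise with a guard epsilon of 1e-6 × the ERK maximum.  The mask is
the ERK channel thresholded by the Huang–Wang fuzzy-entropy criterion
— an exhaustive scan over all 256-bin histogram splits minimizing
Σ h(g)·S(μ(g)) with membership μ(g) = 1/(1 + |g − mean_class|/range)
and Shannon entropy S, the algorithm behind FIJI's "Huang" method —
followed by border-connected hole filling (4-connectivity).  Ties on
entropy plateaus (runs of empty bins) are broken toward the first
minimum with a 1e-9 relative tolerance so the result is deterministic
across arithmetic orderings.  ROI means are computed over mask∩ROI;
an ROI with no in-mask pixels is reported missing, never zero.  Clutch
normalization divides every measurement by the maximum pixel of the
clutch's reference-group average ratio image.  Elastic registration is
out of scope: inputs are assumed co-registered, which the synthetic
pairs are by construction.

## 4. Swim behavior

Speeds are finite-difference displacements over frame intervals,
assigned to the interval start; gaps longer than 3× the median frame
interval break the differencing (no teleport speeds).  Speeds are
floored at 1e-3 mm/s so geometric means remain defined for stationary
animals.  The startle window is the first second after stimulation and
the cruising window the last 60 s of the 2-min recording; both are
summarized by geometric means and compared on log2 speeds (Welch t).
The original assay's manual still / half-active / active scoring is
replaced by a documented surrogate: the fraction of frames above a
speed threshold (default 1 mm/s), binned at 0.25 and 0.75.  For
half-active animals a flag records whether the majority of active
frames fall in the first half of the session.  Repetition trends
regress log2 speed on repetition index.

## 5. Synthetic-data generators

The generators define the study conditions for every test; they emit
the post-segmentation / post-tracking representations the pipeline
consumes (SWC trees, event tables, aligned image pairs, trajectories),
not raw microscopy or video.

**Neurons.**  A spherical soma (lognormal radius, mean 6 μm, CV 0.10)
sprouts 3 stems that grow as chains of lognormal segments (mean 8 μm,
CV 0.30) with a random-walk direction; after each segment the tip
bifurcates with probability 0.18 (up to centrifugal level 5),
terminates with probability 0.10, or extends.  Stem diameter averages
1.3 μm with Rall-style multiplicative taper 0.85 at branch points.
Segment-level diameter statistics are not reported for the real
neurons, so these defaults are calibrated to the published summaries
instead: they give ~800 μm total neurite length, length-weighted mean
diameter ~1 μm, ~15 terminal points, and a neurite:soma surface
partition of ~5, the regime described for the profiled forebrain
neurons.  Triploidy is a *deterministic rescaling* of the seed-matched
diploid draw — soma radius ×1.5^(1/3), every neurite chord ×1.95 (a
uniform dilation about the soma centroid followed by a rigid per-stem
shift onto the rescaled soma surface, which keeps all within-arbor
chords exact), neurite radii ×√(1.5/1.95) — so branching topology is
unchanged and the compartment folds are analytic: soma V ×1.5, soma A
×1.5^(2/3), neurite V ×1.5, neurite A ×√(1.5·1.95).  An independent
draw per ploidy is available by using different seeds.  With frusta the
area fold is exact only for cylinders; the default taper introduces a
relative deviation below 1e-4, and the exactness tests use taper 1.

**Flow.**  Diploid tubes hold 20,000 cell singlets with phase mix
G0 0.45 / G1 0.25 / S 0.15 / G2 0.10 / M 0.05 (free defaults — tests
use recovery against truth labels, not these numbers), DNA at the phase
mean (S uniform between 1× and 2× G1) times lognormal noise of CV 0.05
(a typical Hoechst CV), markers from phase-mapped log10-normal
components (G0→PCNA-neg, S→PCNA-punctate, M→pH3-pos, G1/G2→diffuse),
20,800 beads with 4% CV, 4% doublets (sums of two cells with ~1.9×
width ratios), and 5% sub-G1 debris.  Triploid tubes multiply DNA
means by 1.5 and hold 1/1.5 as many cells, encoding the observed
count decrease; 6 brains pool into each tube.

**Images.**  An elliptical "brain" of uniform ERK intensity over a
dark background; pERK equals ERK times a per-ROI activity fold;
independent Gaussian noise on both channels.

**Swim.**  Two-mode lognormal speeds (startle 20 mm/s for 1 s, cruise
5 mm/s, CV 0.3) with a smooth random-walk heading at 30 Hz for 120 s
in a 100 mm arena; a configurable fraction of animals is permanently
still.

**What the generators do not emulate:** spectral spillover and
compensation, instrument drift within a run, autofluorescence,
non-elliptical brain shapes or registration error, neuron-type
mixtures, and tracking identity switches.  Passing tests therefore
demonstrate correctness of the analysis chain under the stated
statistical structure, not robustness to every artifact of real data.

## 6. Problem sizes and determinism

Default verification sizes — 50 neurons per ploidy, 20,000 cells per
tube, 6 samples per ploidy, 5 seed replicates — were chosen so each
estimate's Monte-Carlo error sits well inside the tolerance being
checked while a full run stays in the seconds-to-minutes range.  Every
stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one manifest seed, and identical (config, seed) reruns
are bit-identical.

## 7. Known limitations

* The soma model is a sphere; real reconstructed somata are irregular,
  so absolute soma surface is approximate (folds are unaffected by
  construction).
* The DJF S-ridge penalty trades a small amount of S-weight shrinkage
  for identifiability; under heavily S-skewed histograms the weight may
  be underestimated by up to ~0.01.
* The activity-class surrogate is a thresholded stand-in for manual
  scoring; its bins (0.25/0.75) are conventions, not measurements.
* ANCOVA-style line comparisons assume homoscedastic residuals across
  stages.
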