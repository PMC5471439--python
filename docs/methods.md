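# Methods

## The quantitative model

The experiment compares tdTomato-labeled cell counts in a fixed
350 × 350 × 100 µm test volume of the preBötzinger complex across six
conditions: a constitutive *Dbx1*-Cre line (the cumulative lineage, the
100% reference) and a tamoxifen-inducible line dosed at one of five
embryonic days (E7.5–E11.5), with n = 3 animals per condition. Cells are
classified as neurons or glia purely morphometrically, by soma
cross-sectional area. Three quantitative questions follow:

1. Does neuronal labeling depend on tamoxifen timing beyond chance?
   (shuffle-and-resample test over timepoints)
2. What fraction of the lineage does each timepoint capture?
   (percent of the constitutive mean)
3. How many Dbx1-derived neurons does the whole structure contain?
   (stereological extrapolation of the sampled window)

## Soma-area model and classification

Neuron somata measure 389 ± 102 µm² and glia 88 ± 22 µm² (mean ± SD),
and the two observed distributions do not overlap. Untruncated normals
with those moments *would* overlap (≈3% of neuron draws fall below
200 µm²), so the generator draws from truncated normals: neurons on
[210 µm², ∞), glia on (0, 160 µm²]. One-sided truncation alone would
shift the achieved neuron mean up by ~9 µm²; the generator therefore
re-solves each class's pre-truncation location numerically (Brent's
method on the monotone truncated-mean map) so the achieved mean equals
the nominal mean. The achieved SD contracts slightly — ≈92 µm² for
neurons and ≈21.9 µm² for glia at n = 10⁵ — which is the documented
cost of honoring non-overlap, nominal means, and (approximately) the
nominal spreads simultaneously.

Classification uses a single threshold, default 200 µm², which lies
inside the empty (160, 210) µm² band; equality is assigned to glia so
the rule is a total partition (the boundary case is otherwise
undefined; the choice is arbitrary but tested). Because the truncation
gap straddles the threshold, generated cells are never misclassified —
a designed property of the synthetic layer, not a claim about real
tissue, where areas near the boundary occur.

The histogram-valley detector bins areas at 18 µm² (edges anchored at
zero so binning is sample-independent), takes the two highest-count
local maxima as the modes, and returns the center of the longest run of
minimum-count bins strictly between them; unimodal input yields an
explicit no-break result rather than an arbitrary number. On 1049-cell
mixtures weighted 92:70 glia:neurons it localizes the break at
≈180 µm², within one bin of the 190 µm² reference; the exact value
inside the empty band is not identifiable from data by construction.

## Image synthesis and morphometry

Somata are rendered as solid, axis-aligned spheroids (equatorial radii
a = b chosen so πab equals an area-model draw; polar radius 0.75 a,
emulating mild axial flattening) at voxel centers, in 16-bit grayscale,
one channel. Dendrites and fibrillar processes are not rendered: only
soma area feeds the analysis. Optional Gaussian blur (µm) emulates the
PSF and optional Poisson noise emulates shot noise at a given
full-intensity photon count. Cells are placed uniformly at random with
non-overlapping bounding spheres (2 µm clearance); real tissue is
likely spatially structured, so passing tests validate the measurement
chain, not any spatial statistics.

Segmentation thresholds at a fraction (default 0.5) of the stack
maximum, labels 26-connected 3-D components, rejects components under
50 voxels (~4.6 µm diameter sphere at 1 µm voxels), and keeps
border-clipped cells when their centroid is inside the volume. Soma
area is the maximum single-plane cross-section of the component —
pixel count × voxel² maximized over z — approximating measurement at
the widest confocal plane.

**Voxel size and area accuracy.** The default volume uses 1 µm
isotropic voxels, matching the 1-µm z-step of the emulated acquisition.
At that sampling, the max-over-z pixel-count measurement carries
discretization error that can reach ~13% for the smallest glia
(counts and classes are still recovered exactly on noise-free,
non-overlapping stacks). Per-cell area accuracy better than 5% requires
sub-micron in-plane sampling — real confocal pixels at 40×/1.15 NA are
~0.3 µm — so the morphometric-recovery validation renders at 0.5 µm
isotropic voxels, where the measured worst-case per-cell error is ~3%.

## Count generation

Per-animal counts are normal draws with the condition's mean/SD,
rounded to the nearest integer and clipped below at zero (relevant when
mean − 3 SD < 0, as at E11.5). Only mean ± SD at n = 3 is specified by
the design, so the normal is a modeling choice; SD = 0 degenerates to
exactly the rounded mean, which the tests exploit. Large cohorts
(n = 300/condition) recover design means to within sampling error,
i.e. the generator is unbiased; a fixed relative tolerance would be
meaningless for the low-mean conditions, whose standard error at any
practical n exceeds 1% of the mean.

## Resampling test

All 15 inducible-line counts are pooled; each of 10,000 resamples
applies a fresh uniform permutation and deals the values back into the
five groups of three (sampling without replacement within a shuffle).
Per timepoint, the 99% band is the (α/2, 1 − α/2) pair of
linear-interpolation empirical quantiles of its resampled means;
significance is the observed mean falling strictly outside its band.
The empirical P value is the doubled one-sided tail probability of the
timepoint's own resampled-mean distribution with an add-one correction,

    P = min(1, 2·min(P_lo, P_hi)),   P_hi = (1 + #{resampled ≥ obs}) / (1 + N),

so P is never zero and P < α agrees with the band rule up to
Monte-Carlo ties. A centered two-sided count against the pooled grand
mean was considered and rejected: the null distribution of three-value
means from this pooled multiset is markedly asymmetric, so a
grand-mean-centered statistic misorders tail areas at the nadir
timepoint and disagrees with the band criterion the test is defined by.
The same machinery can be applied to glia counts (no timepoint is
expected to escape its band). Unbalanced group sizes are rejected
rather than silently generalized.

The exact-enumeration oracle walks every distinct split of the pooled
index set into the group structure (index-level enumeration weights
duplicate values correctly) and returns each timepoint's exact
group-mean distribution; it refuses beyond 12 pooled values
(455 × C(12,3)-scale enumeration is the practical limit of usefulness).
Monte-Carlo CDFs converge to the exact CDFs (sup-norm < 0.02 at 10⁵
resamples), and under a null generator the per-day false-flag rate
stays at/below the nominal α plus Monte-Carlo tolerance — slightly
conservative, as the strict-inequality rule on a discrete null implies.

The two-sample soma-area comparison is Welch's t by default (pooled
variance on request; the variance ratio between classes is ~20, so
Welch is the defensible default); mutually constant equal groups return
P = 1 by convention.

## Extrapolation

`total = mean × (rostrocaudal_extent / sampled_depth) ×
bilateral_factor`, default 440/100 and factor 2; with the reference
window mean of 63 neurons this gives 554.4 (displayed ~554). The
bilateral factor is exposed rather than hardwired because the sampled
window is unilateral while the structure is bilateral; uniform
rostrocaudal density is assumed. The printed integer mean 63 is used
for the headline number; per-timepoint percentages are computed
unrounded, which is why displayed percentages can differ by 1–2 points
from ratios of rounded means (23/70 → 32.9% vs a printed 34%).

## Pipeline and reproducibility

A single YAML/JSON config nests all stage parameters; the embedded
reference preset reproduces the full design with one command. Every
stochastic operation takes an explicit seed; the pipeline derives
independent per-stage/per-animal substreams from the run seed via seed
sequences, so runs are byte-identical under a fixed config and seed.
The imaging-level runner renders one stack per animal, segments and
classifies it, and feeds the *recovered* counts into the same
downstream stages, reporting per-animal recovery error; with blur and
noise disabled recovery is exact for non-overlapping cells.

Problem sizes in the validation suite — 100-cell stacks, 100 simulated
cohorts for the significance rate, 1000 null cohorts at 2000 resamples
for the type-I check — were chosen as the smallest sizes at which the
Monte-Carlo tolerances above are meaningful.

## Known limitations

- Absolute counts (70 ± 1, 63 ± 4, …) are properties of real tissue;
  the package treats them as generator parameters and validates
  parameter recovery, not the values themselves.
- The renderer places cells uniformly at random; no rostrocaudal
  density gradient, laminar structure, or vascular exclusion is
  modeled.
- No immunostaining channels, marker colocalization, or process
  morphometry; classification is area-only.
- The resampling test requires a balanced design, as in the experiment
  it models.
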