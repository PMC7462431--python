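# Methods

## The problem

Source-projected EEG functional connectivity (FC) is contaminated by volume
conduction: electric fields spread instantaneously through head tissue, so
reconstructed regional time courses mix, producing spurious zero-lag
correlations that decay with the Euclidean distance (ED) between regions.
Genuine FC, by contrast, is thought to be mediated in large part by
white-matter structural connectivity (SC) — which itself decays with
distance, but not only: strong callosal connections link distant homotopic
regions, and the detailed support of the connectome is not a function of
distance. This package implements a structure-informed augmentation: ROI
signals are spatially low-pass filtered *on the connectome graph*, which
selectively strengthens correlations between structurally connected regions,
together with the full validation machinery needed to decide whether that
operation moves EEG-FC toward a canonical reference network structure.

## The core operator

Given ROI signals x_i(t) and a nonnegative symmetric weight matrix C with
zero diagonal, the smoothed signal is

    x_hat_i(t) = x_i(t) + G * sum_j c_ij x_j(t),

i.e. x_hat = (I + G C) x applied independently at every time point. G >= 0
is the scalar filter weight. The operator is linear, time-pointwise, and is
applied to broadband signals before band-pass/envelope extraction. No
renormalization is applied afterwards: correlation-based FC is invariant to
per-channel scale, so variance growth with G is harmless. For two nodes with
a unit edge and independent unit-variance inputs the filtered correlation is
2G/(1+G²) — the analytic anchor used in tests.

Four graph variants are supported: the consensus SC itself (fiber counts);
a dense ED graph exp(-k·ED); the ED graph masked to the SC support
("ED match"); the ED graph thresholded to the SC's density ("ED dens");
plus a degree-preserving randomization of the SC as a null. Graphs are
max1-normalized by default (divide by the maximum weight) so that filter
weights are comparable across variants; with raw fiber counts the same G
would mean wildly different effective smoothing. The scale k of the ED
graphs defaults to matching the median dense weight to the median nonzero
max-normalized SC weight (closed form: k = -ln(median w)/median ED).

## FC estimation

Power-envelope correlation is the primary measure: zero-phase FIR band-pass
(Hamming-windowed sinc, order ~3·rate/low-edge), Hilbert-transform
magnitude, zero-phase FIR low-pass at 0.5 Hz, Pearson correlation over time.
Two numerical choices matter:

- The forward–backward FIR pass is collapsed into a single FFT convolution
  with conv(h, reversed(h)) on an odd-reflection-padded signal. It matches
  `filtfilt` in the signal interior and is O(T log T) — the 0.5 Hz low-pass
  at 250 Hz has ~1,500 taps, so a direct implementation would dominate all
  run times.
- Two seconds are trimmed from each end of the low-passed envelope before
  correlating. Hilbert and low-pass edge transients are *common across
  channels* and otherwise bias every pairwise correlation upward.

Intervals must be at least 19 s (slow envelopes need that much data);
per-interval correlation matrices are combined by duration-weighted
Fisher-z averaging (the combination rule is not dictated by the problem; z
averaging is the variance-stabilized choice). Coherence and imaginary
coherence come from Welch cross-spectra over five 50 %-overlapping Hann
segments per ~3 s window, averaged over the band's frequency bins; the
imaginary part is antisymmetric across the matrix, so the upper triangle is
mirrored rather than averaged. A ±6 SD amplitude criterion drops artifact
windows before spectral estimation.

## Consensus connectome and search information

The group SC retains, separately for intra- and interhemispheric edges and
within equal-count ED bins (default ceil(sqrt(#candidates)) bins), the most
recurrent edges until the class's mean single-subject edge count is reached,
requiring recurrence in at least 30 % of subjects; retained weights are mean
fiber counts over the subjects having the edge. Distance-binned,
class-separate retention prevents a single global threshold from wiping out
the sparser interhemispheric edges.

Search information quantifies how "hidden" the shortest path between two
nodes is: with edge lengths 1/weight (config-switchable to -log of the
max-normalized weight), S(s→t) = -log2 of the product, over path nodes i,
of w(i→next)/strength(i). It is symmetrized by arithmetic mean for use as a
dense pairwise SC predictor. S is invariant to global rescaling of weights
and roughly inversely related to fiber count.

## Structure–function statistics

Every unordered ROI pair is a sample. The stepwise Gaussian GLM regresses
FC on ED, search information, relative regional variance (RRV: per-ROI
variance normalized to each subject's maximum, then averaged over subjects)
and ROI size, plus all first-order interactions. Terms enter when the
deviance-difference chi-square test (dispersion estimated from the larger
model) gives p < 0.05, leave at p > 0.10, and interactions are admitted only
while both mains are present; predictors are standardized internally. Nodal
RRV and ROI size reduce to pair level by the mean of the two ROIs' values
('min' available). Entry/removal thresholds mirror the defaults of standard
stepwise-GLM tools.

The distance-matched comparison splits the ED overlap of SC-connected and
unconnected pairs into 10 equal-count bins, subsamples the larger class per
bin to the smaller's count (100 draws by default), and applies a Wilcoxon
signed-rank test to per-subject mean differences, Bonferroni-corrected over
bands. Matching controls the ED *distribution* to bin resolution only;
residual within-bin distance confounds are not removed, so calibration
guarantees hold under exchangeable nulls (FC independent of class given the
bin), which is what the type-I tests check.

## Community structure

Louvain is run on the signed modularity objective with resolution γ
(positive and negative weights weighted asymmetrically, the standard signed
choice; zeroing negatives is available — how negatives were treated is
genuinely open, hence the switch). Because bctpy is not available in the
environment, the optimiser is implemented here as a generic
modularity-matrix Louvain (greedy local moves + aggregation); on nonnegative
matrices it reproduces networkx's partitions and modularity, which serves as
the independent cross-check in tests. 200 repetitions with independent seed
substreams give a co-assignment ("community") matrix; community structures
of two FCs are compared by per-ROI Spearman correlation of co-assignment
profiles (diagonal excluded, constant profiles dropped), averaged over ROIs.
The (γ, G) sweep reports agreement and community-count surfaces, the best G
per γ, and flags the Pareto set in (higher agreement, fewer communities);
it does not hard-code a preferred community count.

## The synthetic cohort — what it emulates and what it does not

There is no public generative model for this kind of data, so the generator
states one explicitly. All of its defaults are stated here; they define the
world the end-to-end tests live in and are not revisited.

- **Geometry.** Two hemispheric shells (radius 55 mm, centers ±35 mm along
  x), left hemisphere rejection-sampled with ≥8 mm spacing, right hemisphere
  its mirror image plus 2 mm jitter, so every ROI has a homotopic partner.
  ROI sizes log-uniform in [50, 1500] voxels. Default N = 68.
- **Connectomes.** Group edge probability 0.95·exp(-ED/60 mm), multiplied
  by 0.3 across hemispheres; homotopic pairs connect with probability 0.9
  and carry a +120 fiber-count boost — the callosal structure that distance
  alone cannot mimic, and the reason a structural mask contains information
  beyond ED. Fiber counts ~300·exp(-ED/60) with log-normal dispersion 0.5;
  subjects drop/add edges at noise-scaled rates. The resulting consensus
  densities (~28 % intra, ~8 % inter at the defaults) sit in the range
  reported for tractography cohorts, and the ED–search-information
  correlation (~0.5–0.6) matches the empirically reported coupling.
- **Sources.** Per ROI, white noise band-passed to the target band
  (default beta, 13–30 Hz), amplitude-modulated by an independent slow
  (<0.5 Hz) log-normal envelope of depth 0.5, generated with a one-kernel
  margin and cropped to the stationary middle (edge variance inflation of
  the very long 0.3 Hz kernel would otherwise correlate all channels).
  Genuine coupling: s = (I + coupling·rownorm(SC)) z with coupling = 1 —
  instantaneous linear mixing along SC, keeping the ground truth analytic
  (no conduction delays).
- **Leakage.** y = K s with K = rownorm(exp(-ED/30 mm)) — a fixed
  instantaneous spatial kernel, not a lead-field; only ED-dependent
  zero-lag mixing is required of it. 30 mm makes ED dominate the observed
  FC, as it does empirically.
- **Reference.** The fit analyses need a canonical leakage-free reference,
  playing the role a large independent fMRI group FC plays in practice. It
  is the Fisher-mean envelope FC of 30 *independent* subjects drawn from
  the same group structural backbone, leakage-free, with coupling 5× the
  EEG cohort's. Both independence and the stronger coupling are essential,
  not cosmetic: an in-cohort reference shares each subject's envelope
  sampling noise with the observed FC and makes the unfiltered baseline
  unbeatable by construction, and a reference that expresses SC-mediated
  coupling no more strongly than the EEG does leaves the filter nothing to
  recover — the premise of the method is precisely that structurally
  mediated correlations are *underestimated* in leaky band-limited
  envelopes relative to the reference modality.
- **Cohort shape.** 18 subjects, 2–5 intervals of 20–60 s at 250 Hz.
- **Controls.** White Gaussian noise matched per ROI and interval to the
  observed sample variance exactly.

What a green end-to-end test establishes: on SC-coupled,
leakage-contaminated linear sources, graph filtering at moderate G raises
the fit to an independent leakage-free reference above the unfiltered
baseline, the SC-masked-ED graph does so at least as well as the dense-ED
graph, and community agreement improves likewise. What it does not
establish: anything about nonlinear neural dynamics, realistic lead fields,
1/f spectra, task structure, or the magnitude of the effect in real data —
the generator is linear and instantaneous throughout.

In this synthetic world the filter-weight scale differs from raw-fiber-count
conventions: graphs are max1-normalized with row sums of ~5–15, so the
transition regime sits at G ≈ 0.05–1 and the synthetic analyses use the grid
{0, 0.05, 0.1, 0.2, 0.4, 1}; the configuration default for empirical-style
pipelines spans 0–1,000.

## Numerical conventions and degenerate inputs

- Correlations are clipped to ±(1 − 1e−15) before atanh; |r| = 1 (e.g.
  self-comparison) is clipped to z ≈ 17.8 and flagged.
- Constant channels yield correlation entries of 0 with a warning; constant
  FC matrices make a fit undefined and raise.
- Ties when thresholding ED pairs ("ED dens") break by lexicographic ROI
  pair order; rank-normalization uses average ranks, so an all-tied input
  maps to all zeros.
- All-zero signed-rank differences report p = 1 with a degenerate flag
  rather than erroring.
- Every stochastic routine takes a single integer seed and derives
  independent substreams (numpy SeedSequence); sweeps derive one
  deterministic seed per (γ, G) grid point so any single cell is
  reproducible in isolation.

## Known limitations

- The generator is fully linear/instantaneous; effect sizes in it cannot be
  read as predictions for real cohorts.
- Search information follows the random-walker convention with inverse
  weights as lengths; the literature is not unanimous on the edge-length
  map (the -log alternative is provided).
- Distance-matched comparisons are calibrated under exchangeable nulls
  only (see above).
- Louvain repetitions randomize the optimisation path (node visiting
  order), which for near-degenerate modularity landscapes may underestimate
  partition variability relative to fully random restarts.
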