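# Methods

`apexprof` quantifies where a fluorescent reporter protein sits along the
apical–basal axis of the *Arabidopsis* shoot apical meristem (SAM) in
confocal z-stacks, and classifies how genes respond over a developmental
time course into two regulatory modes. This note documents the models,
the defaults and the numerical choices, and what the synthetic validation
does and does not establish.

## Imaging model and procedure

A meristem is imaged mounted on its side, so the stack z axis approximates
the apical–basal axis. The analysis chain is:

1. **Apex detection** (`maskfit.detect_apex`). The structural (cell-wall
   stain) channel is thresholded with Otsu's method; the topmost
   above-threshold voxel of each (y, x) column gives a surface depth map,
   which is median-filtered (3×3) to suppress single-column noise. The apex
   column is the global minimum-depth point within the central half of the
   field; because a shallow dome produces a flat plateau in the discrete
   depth map, the plateau member nearest the plateau centroid is taken.
   The apex z is refined to the midline of the contiguous foreground run in
   that column (the centre of the stained wall), which removes the
   half-shell-thickness bias of the raw topmost voxel.
2. **Paraboloid fit** (`maskfit.fit_paraboloid`). Surface points are
   extracted in the two orthogonal midplanes through the apex (±25 µm by
   default) and each plane receives a one-parameter least-squares fit
   z = z_apex + c·(u−u0)² with the apex held fixed. Curvatures must be
   positive (a dome); a flat or inverted surface is an error.
3. **Masking** (`maskfit.build_mask`). A voxel is kept iff it lies at or
   below the fitted surface (closed boundary; an optional margin admits a
   skin above it) and within a lateral cutoff radius of the apex axis
   (default 40 µm). The cutoff excludes bright signal in cauline-leaf
   axils, which would otherwise contaminate deep slices. The mask grows
   monotonically with margin and cutoff.
4. **Profile extraction** (`axialprofile.extract_profile`). The reporter
   channel is collapsed to a 1D depth profile: for each slice at or below
   the apex, the sum of reporter intensities over masked voxels ("sum of
   the slices"; a per-slice mean is available by flag). Depth 0 is the apex
   slice; spacing is the z-step (0.4 µm by default).
5. **Smoothing** (`axialprofile.smooth_profile`). A robust local quadratic
   (degree-2 LOESS): at each sample a quadratic is fitted by weighted least
   squares to the nearest `ceil(span·n)` samples with tricube weights
   (span 0.25 by default), followed by two bisquare robustness iterations
   (Tukey biweight on residuals scaled by 6× the median absolute residual).
   The bisquare scale is floored at 1e-9 of the data maximum so that
   machine-precision residuals on exactly quadratic data cannot zero out
   all weights. A pure quadratic is reproduced exactly; statsmodels'
   `lowess` is degree-1 only, which is why the filter is implemented here.
6. **Domain metrics** (`axialprofile.locate_peak`, `detect_boundaries`,
   `integrate_domain`). pos(Imax) is the depth of the profile maximum
   (ties broken toward the apex). Scanning outward from the peak, the
   domain boundaries ini(ED) and end(ED) are the linearly interpolated
   depths at which the profile first reaches 10% of its maximum
   (threshold fraction configurable). A side that never falls below the
   threshold is clamped to the sample nearest the threshold — ties
   resolved away from the peak, so a flat plateau extends the domain to
   the data limit — and flagged `clamped-to-nearest`. For a Gaussian
   axial profile of spread σ the extent converges to 2σ·√(2 ln 10) ≈
   4.29σ, and the domain captures erf(√(ln 10)) ≈ 96.8% of the profile
   mass. Total intensity is the sum of profile samples within the closed
   boundary interval.

All depth metrics are invariant under rescaling of the reporter channel;
total intensity is homogeneous of degree 1.

Group comparison of per-meristem metrics uses the two-sided Mann–Whitney U
test: exact by full enumeration of the null U distribution for tie-free
samples with combined n ≤ 12, and a tie-corrected normal approximation with
continuity correction otherwise. Compact letter displays are built from
maximal cliques of the "not significantly different at α = 0.05" graph.

## Morphometrics

Meristem width is the chord from the axil of the youngest flanking
primordium to the opposite side of the meristem; height is the
perpendicular distance from the central tip to the infinite line through
that chord. The chord — not the image x axis — defines "horizontal", a
deliberate choice that makes both measures invariant to mounting
orientation; landmarks are supplied, not auto-detected. Group comparisons
use one-way ANOVA with Tukey's HSD for normally distributed measures, or
Kruskal–Wallis with Dunn's pairwise comparisons (Bonferroni-adjusted)
otherwise, each summarised with a compact letter display.

## Two-mode transcriptomic workflow

Inputs are per-contrast DE tables (gene id, log2 fold change, BH-adjusted
p) produced upstream by a count-based DE engine; expression matrices are
analysed as log2(FPKM+1). The workflow:

1. call DEGs at adjusted p < 0.05 (no fold-change cutoff; both
   configurable) per genotype and timepoint contrast against the day-7
   baseline;
2. take the set difference mutant ∖ wild type per timepoint
   (mutant-specific DEGs), then partition the two timepoint sets into
   exclusive and shared parts (the Venn counts);
3. assemble the union genes' mutant-vs-wild-type log2 fold changes at
   days 7/10/13 into a genes × timepoints matrix (genes missing from any
   contrast are dropped and reported);
4. cluster trajectories by agglomerative hierarchical clustering
   (complete linkage, Euclidean distance, fixed-k tree cut, k = 5 by
   default). Rows are sorted by gene id before linkage so equal-distance
   merges resolve identically regardless of input order; the fixed-k cut
   is an explicit, reproducible substitute for a visual heatmap cut;
5. classify each cluster's mean trajectory: **ectopic** if the mean
   log2FC at the first post-baseline timepoint is ≥ 2 (strong early
   activation of genes normally silent in this tissue); **gradual** if the
   mean is monotonically non-decreasing with a final value in [0.5, 2)
   (accelerated activation of floral-transition promoters); otherwise
   **other**. Clusters below 5 genes are flagged and left unclassified —
   fixed-k cuts routinely produce one- or two-gene clusters that carry no
   trend information;
6. optionally test the DEG union for enrichment of an externally supplied
   bound-target list with Fisher's exact test, alternative "greater"
   (upper hypergeometric tail); the odds ratio uses a 0.5 continuity
   correction, flagged, when a cell is zero.

## Synthetic data

The generators provide every input with exact ground truth, because real
acquisitions of this kind are not redistributable at test scale.

**Stacks.** A downward-opening paraboloid surface (curvatures cx = cy =
0.02 µm⁻¹ by default) carries a thin bright shell (structural channel);
the reporter is a separable Gaussian domain — axial spread σ_ax, lateral
spread σ_lat, amplitude A — confined to the dome interior over a constant
background, with Poisson shot noise plus additive Gaussian read noise,
digitised to 16 bits (saturation above 0.1% of voxels raises a warning;
negative noise excursions clip silently). The Gaussian form is a modelling
choice that yields closed-form checks of the 10% rule; real domains are
not Gaussian, the shell has no point-spread blur, and there is no
cell-scale texture — so passing recovery tests demonstrates correctness of
the measurement chain, not robustness to real optics. Defaults: voxel
0.3 × 0.3 × 0.4 µm, domain depth d0 = 50 µm, σ_ax = 15 µm, σ_lat = 12 µm,
A = 2000, background 5, Gaussian sd 10 — an amplitude/offset ratio typical
of a detector-offset-subtracted acquisition; with a large constant offset
the per-slice background mass would exceed 10% of the summed peak and the
threshold rule would degenerate to its clamped fallback. The truth sidecar
records the apex, d0, the analytic 10% half-width σ_ax·√(2 ln 10) and the
noise-free domain signal inside the 10% band.

**Expression tables.** Three archetypes: unregulated background; a
"gradual" archetype with mutant-vs-wild-type log2FC trajectory (0, 0.5, 1)
over days 7/10/13; an "ectopic" archetype with trajectory (0, 4, 2).
Default sizes 3000/535/40. Trajectory noise is Gaussian (sd 0.3).
Adjusted p-values are drawn directly — Uniform(0,1) under the null,
Beta(0.02, 1) under the alternative (≈94% of regulated genes fall under
p < 0.05) — because the DE engine itself is out of scope; only the shape
of its output matters downstream. Bound-target flags are drawn at rate
0.3 for regulated and 0.05 for background genes, two rates rather than
one so that the enrichment test has a signal to detect.

**Landmarks.** Width/height truth is constructed analytically and the
set is rigidly rotated and translated; each set draws from its own child
seed so pose randomisation cannot shift the size draws.

## Problem sizes and numerical checks

The end-to-end recovery battery uses 50 stacks at 1 × 1 × 0.4 µm voxels,
71 × 71 columns and an adaptive slice count covering d0 + 2.8σ_ax, with
d0 ∈ [40, 120] µm and σ_ax ∈ [10, 40] µm — the depth range spanning
vegetative through inflorescence stages — at amplitude 2000 (SNR well
above 5). Median peak-depth error is required to stay within one z-step
and median relative extent error within 10%; the extent bias is dominated
by the constant-background offset of the 10% threshold and by lateral
truncation of shallow domains by the dome. Statistical routines are
checked against brute-force oracles: full rank-permutation enumeration
for the exact Mann–Whitney p (combined n ≤ 10), explicit hypergeometric
tail sums for every 2 × 2 Fisher table with N ≤ 40, and exhaustive
agglomeration for complete-linkage merge heights at n ≤ 8.

## Limitations

Quantities that depend on the original raw data are **not recomputable**
here and are not claimed: absolute cluster sizes from a real transcriptome
(e.g. how many genes fall in each trajectory cluster), enrichment
p-values against real ChIP target lists, and the micrometre depths and
extents of real meristems at particular developmental stages. The
synthetic suites validate the procedures — set algebra, boundary rule,
recovery, oracle agreement — not those biological numbers. Further known
limits: depth is measured along the stack z axis (no geodesic correction
for dome curvature); the mask is a single paraboloid (one meristem per
stack); boundary interpolation assumes a locally linear profile between
samples; and the fixed-k tree cut can split or merge clusters that a
human inspecting a heatmap would draw differently.
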