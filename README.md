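# apexprof

Quantification of reporter-protein distribution along the apical–basal
axis of the *Arabidopsis* shoot apical meristem (SAM) in confocal
z-stacks, plus the downstream "two modes of gene regulation" time-course
transcriptomic workflow. It is written for plant developmental biologists
who image reporter lines through floral transition and want reproducible,
scriptable measurements instead of ad-hoc notebook code.

## What it computes

**Imaging.** For each z-stack (structural cell-wall channel + reporter
channel) the pipeline detects the meristem apex, fits a downward-opening
paraboloid z = z_apex + cx(x−x0)² + cy(y−y0)² to the dome surface in the
two orthogonal midplanes, masks out everything above the surface and
outside a lateral cutoff (boundary/axil signal), collapses the masked
reporter signal to a depth profile I(d) by summing each slice, smooths it
with a robust local quadratic (degree-2 LOESS) filter, and reports the
expression-domain metrics

- `pos(Imax)` — depth of the profile maximum below the apex (µm),
- `ini(ED)`, `end(ED)` — apical and basal domain boundaries, the
  interpolated depths where I(d) falls to 0.1·Imax (a side that never
  falls below the threshold is clamped to its nearest sample and flagged),
- extent = end(ED) − ini(ED) and the total intensity
  Σ I(d) over [ini(ED), end(ED)].

For a Gaussian axial domain of spread σ the extent converges to
2σ·√(2 ln 10) ≈ 4.29σ. Group comparisons use the two-sided Mann–Whitney
U test (exact for small tie-free samples) with compact letter displays;
landmark-based width/height morphometrics with ANOVA–Tukey or
Kruskal–Wallis–Dunn comparisons are included.

**Transcriptomics.** From per-contrast DE tables (gene, log2FC, adjusted
p), the workflow calls DEGs (padj < 0.05), forms mutant-specific sets
(mutant ∖ wild type per timepoint), partitions them across timepoints,
assembles mutant-vs-wild-type log2FC trajectories, clusters them
(hclust-style complete linkage, Euclidean, fixed-k cut), and labels each
cluster **gradual** (monotone rise to log2FC ≈ 1) or **ectopic** (log2FC
≥ 2 already at the first post-baseline timepoint), with one-sided Fisher
tests for bound-target enrichment.

A synthetic-data module generates two-channel meristem stacks, DE tables
and landmark sets with exact ground-truth sidecars, so the whole pipeline
is testable without any raw acquisitions. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

```python
import apexprof as ap

params = ap.StackParams(nx=71, ny=71, nz=250, dx=1.0, dy=1.0, dz=0.4,
                        cx=0.02, cy=0.02, apex_iz=8,
                        d0=50.0, sigma_ax=15.0, sigma_lat=10.0,
                        amplitude=2000.0, seed=1)
stack, truth = ap.generate_stack(params)

structural, reporter = stack.get_channel(0), stack.get_channel(1)
apex = ap.detect_apex(structural)
model = ap.fit_paraboloid(structural, apex, halfwidth_um=25.0,
                          cutoff_radius_um=30.0)
mask = ap.build_mask(model, structural)
profile = ap.smooth_profile(ap.extract_profile(reporter, mask, apex))
m = ap.quantify_profile(profile)
print(f"pos(Imax) {m.pos_imax:.1f} um  (truth {truth.d0:.1f})")
print(f"extent    {m.extent:.1f} um  (analytic {2*truth.half_width_10pct:.1f})")
```

prints

```
pos(Imax) 50.0 um  (truth 50.0)
extent    66.0 um  (analytic 64.4)
```

i.e. the peak of a domain placed 50 µm below the apex is recovered on the
z-grid, and the measured 10% extent is within ~3% of the closed-form
Gaussian width — the residual comes from the constant background offset
and voxel discretisation.

The same chain is available from the shell:

```sh
apexprof simulate stack --seed 1 --out stacks/s.tif
apexprof quantify --input-dir stacks --out run1     # writes metrics.tsv
apexprof simulate expression --seed 1 --out tables
apexprof degmodes --tables-dir tables --out run2    # partition, clusters, modes
```

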