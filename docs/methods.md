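# Methods

## The estimation problem

The quantity of interest is the fraction of a seed's interior occupied by
microcracks. With tomographic cross-sections in hand this is an area
fraction per section, averaged over sections. The package estimates it by
point counting — the classical stereological device: points thrown
uniformly at a region hit a sub-region with probability equal to its area
fraction, so the hit rate is an unbiased estimator with binomial-type
error that shrinks as 1/√N.

### Point classification

Each accepted point scores ξ = 1 (solid), 0 (crack) or 0.5 (crack
boundary). The per-section coefficient K_md_i = 1 − mean(ξ) then estimates
the weighted area fraction (damage + ½·boundary)/object. Points proposed
on the image background are rejected and regenerated and never count
toward N: the sampling domain is the object itself, which is what makes
the estimator unbiased for the within-object fraction regardless of how
much background the image contains.

Two readings of the sampling step are defensible — a regular lattice of
test points or pseudo-random uniform points. The statistical treatment
(a variance, a normal-quantile confidence interval) presumes independent
random points, so that is the implementation: continuous uniform
coordinates over the image rectangle with rejection of background.
Continuous coordinates also resolve the "point exactly on a boundary"
corner case: a real-valued point lies on a pixel edge with probability
zero, so ξ = 0.5 arises only from pixels explicitly labelled boundary
(see below), never from geometric edge hits.

### Uncertainty

The section estimate carries the plug-in variance
D_ξ = mean(ξ²) − mean(ξ)² and the Wald-type half-width
x_β·√(D_ξ/N), with x_β the two-sided standard-normal quantile
(scipy's `norm.ppf((1+β)/2)`; 1.96 at β = 0.95). At the default working
point N = 3400 and damage fractions of a few percent, np ≫ 10, so the
normal approximation is comfortable; the acceptance suite verifies
empirical coverage of 92–97% at β = 0.95 over 500 independent runs. The
specimen-level half-width propagates the per-section variances through
the mean: x_β·√(Σ_j D_j/N)/J. Variance of a {0, ½, 1} variable is
bounded by ¼, so half-widths are bounded a priori.

Degenerate sections are exact, not approximate: a crack-free section
yields K_md_i = 0 for every seed, a fully damaged one yields 1.

### Aggregation and the oracle

The specimen coefficient is the arithmetic mean of the per-section
coefficients over J sections (J = 20: ten horizontal, ten vertical; any
J ≥ 1 is accepted). The reference value K_fmd — physically a damage
volume over object volume — is implemented as its per-section area
analogue by exact pixel counting, aggregated the same way (mean of
per-section fractions), so estimator and oracle target the identical
quantity and differ only by Monte Carlo error. A volumetric (liquid
displacement) measurement is out of scope by design.

## Label masks and the boundary band

Segmentation partitions every section into background / solid / damage /
boundary (codes 0–3 in label TIFFs). On a raster the solid–damage
interface has no area, so "boundary" is operationalized as an optional
band: in-object pixels within chessboard distance `band_px` of a pixel
of the opposite class are relabelled boundary, on both sides of the
interface. The default band is 0 (two-class estimation); a nonzero band
gives ξ = 0.5 concrete support and the ground-truth bookkeeping weights
those pixels by ½ so the oracle stays consistent.

## Segmentation

The pipeline assumes a cracks-dark rendering; stacks flagged
cracks-bright are intensity-inverted on ingest (idempotent). Steps:

1. **Object support** — global threshold against the background level
   (Otsu over the whole slice unless a fixed intensity is given), largest
   8-connected component, internal holes filled. A seed section is a
   single solid body; hole filling keeps internal cracks from being
   mistaken for background.
2. **Cracks** — a second threshold within the support (Otsu over
   in-object intensities unless fixed); in-object pixels at or below it
   are damage.
3. **Speckle filter** — connected damage components smaller than
   `min_speckle_px` (default 5) revert to solid, suppressing
   noise-induced false cracks.
4. Optional boundary band as above.

For an automatic (Otsu) crack threshold, a minimum solid-vs-crack
mean-contrast guard (default 20 intensity levels) prevents the
thresholder from splitting pure noise in a crack-free section; a fixed
threshold bypasses the guard. Thresholding is monotone: raising the
crack threshold never decreases the damage-pixel count.

No published delineation procedure exists for the real tomograms this
emulates; this pipeline is a reasonable, fully specified stand-in, and
every accuracy claim about it is made against phantoms only.

## The phantom generator

Synthetic sections stand in for CT data that cannot ship with software.
The body is an ellipse with default 12.6 × 8.5 mm axes — mid-range of
measured corn-kernel length (12.09–13.11 mm) and width (8.02–9.07 mm) —
rasterized at 0.05 mm/px into a 220 × 300 image (≈ 33,600 object
pixels). Real acquisitions resolve micrometres; the coarser raster keeps
every test and the acceptance run fast while preserving the geometry
that matters (thin elongated cracks inside a convex body). The raster
takes three configured intensity levels (background 0, crack 40, solid
200 by default) plus optional Gaussian noise (default sd 6); polarity
can be flipped to cracks-bright to exercise normalization.

Cracks are random-walk polylines (unit steps, Gaussian heading jitter
sd 0.15 rad) dilated to `crack_width_px` (default 2), clipped to an
inner margin of the body so internal damage never touches the
background. Crack length defaults to 0.3 of the major diameter. Pixels
are stamped one step at a time and tallied, and drawing stops the moment
the damage tally reaches the target pixel count, so a slice's realized
fraction tracks its target to within a stamp (a few pixels). Ground
truth is re-tallied from the emitted mask, never assumed.

Two deterministic hooks exist for tests: rectangles of known geometry
instead of random walks, and a fill-the-whole-body mode.

Deliberate simplifications: each section draws an independent 2D crack
field (no coherent 3D crack system — the estimator consumes sections
independently, so 3D coherence would add nothing to its validation); no
CT physics (beam hardening, rings); orientation tags are metadata only.
Passing tests therefore demonstrate estimator and pipeline correctness
on seed-like geometry, not segmentation robustness to real CT artefacts,
and the crack morphology parameters are plausible placeholders, not
calibrated to real kernels.

## The load → damage response

A virtual load scenario (static or dynamic, vertical or horizontal
placement, load fraction f of the critical force F_kr) maps to a target
damage fraction: the baseline fraction (default 0.02) at f = 0.3 rising
monotonically to baseline × fold_span at f = 0.9, interpolated as
1 + (fold − 1)·t^shape on the normalized position t, clamped outside the
anchors. Default fold spans are 6.0 (static) and 3.0 (dynamic) — the
magnitude of dose-response spans reported for real kernels (5.5–6× and
3–3.3×), which the virtual study must be able to encode and recover.
`replicate_noise_sd` scatters per-section targets for
replicate-variability experiments (default 0: the study conditions are
noise-free unless asked otherwise).

## The virtual study

One specimen per (scenario × replicate) cell: generate 20 sections,
segment, estimate, one table row. The grid is 2 load types × 2
placements × 5 load fractions (0.3, 0.45, 0.6, 0.75, 0.9 of F_kr). The
**fold increase** of a group is mean K_md at the highest fraction over
mean K_md at the lowest — the simplest consistent definition of a
"damage increased k times over the load range" summary; comparing
against an unloaded baseline instead would be a different, equally
defensible choice, and is intentionally not mixed in. Trends are
least-squares polynomials of degree ≤ 2 (degree 2 default — the observed
dependencies are smooth and monotone, and no mechanistic curve is
available) with R² reported.

## Numerical and reproducibility choices

- One root seed per specimen; section j samples from stream seed + j;
  study cell k uses root + 9973·k. All generation and estimation is a
  pure function of (inputs, seed); outputs are bit-reproducible.
- Rejection sampling proposes in batches; a budget of
  `max_rejection_factor` (default 10,000) proposals per accepted point
  turns a pathologically sparse mask into an explicit error instead of a
  hang.
- Plug-in variance is clipped at 0 against floating-point cancellation.
- The CLI's default root seed is the fixed constant 20250501 so bare
  invocations reproduce.
- Problem sizes in the test and acceptance suites — the 220 × 300
  default raster, 200 runs for the unbiasedness check, 500 for coverage,
  one replicate per study cell — are chosen so the whole validation runs
  in seconds at the full N = 3400 working point.

## Known limitations

- Wald intervals undercover for very small damage fractions
  (N·p ≲ 10); at the default working point this is immaterial, but
  single-digit-pixel cracks at small N would need an exact binomial
  interval, which is out of scope.
- The automatic crack threshold assumes a bimodal in-object histogram;
  heavily textured real material would need a fixed, calibrated
  threshold.
- A fully damaged object cannot be segmented from intensity alone
  without a prior (there is no solid reference left); the estimator
  handles such masks, but producing them from images requires a fixed
  threshold.
- Fold-increase ratios inherit the baseline's relative Monte Carlo
  error; at baseline 0.02 and N = 3400 × 20 sections × 2 placements the
  end-to-end recovery is comfortably within ±15%, but much smaller
  baselines would need more points or sections.
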