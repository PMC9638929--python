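# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `polyprofile`, in the spirit of a model-description section.

## Peak detection and the location model

A sample is a detected peak when it terminates a run of `min_run` strictly
increasing absorbance values and starts a run of `min_run` strictly
decreasing values (the apex counts toward both runs; default `min_run = 4`).
Ties break a run: "monotonic" is read strictly, which is the simplest
deterministic rule and makes detection exactly mirror-symmetric.  The
detector has no amplitude threshold, so flat noise-only stretches of a trace
can produce spurious maxima (a 4-up/4-down pattern occurs in white noise
with probability ≈ 0.4% per sample, independent of the noise amplitude);
in practice the debris cutoff (`start_position`) and the absence of truly
flat regions in real traces make this a non-issue, but it is why the test
fixtures tilt or de-noise their baselines.

Detected (or user-supplied) peak positions are fitted to
`x(n) = a·ln(n) + b` by ordinary least squares on ln(index).  The same
relation is sometimes described in the inverse direction (index growing
exponentially with position); the logarithmic parameterisation is fixed here
as the single canonical form.  Subunit peaks enter as fractional indices:
the small subunit at its mass fraction of the full ribosome (0.35 yeast,
0.37 mammal) and the large subunit at the complement (0.65 / 0.63).  The
complement rule for the 60S peak extends the mass-proportionality argument
used for the 40S peak; it is a package choice, not a measured constant.
When peaks are auto-indexed, the first detected peaks past the debris cutoff
are assigned 1, 2, 3, …; if subunit peaks were detected, or peaks are
missing from the middle of the series, the user must supply indices
explicitly — consecutive auto-indexing is the only assumption that needs no
further input, and it fails visibly (large fit RMS) when wrong.

## Constrained Gaussian decomposition

The trace model is `Σ_i s_i·N(x; μ_i, σ_i) + A·e^{−kx} + m·x + c` with peak
centres μ_i fixed at location-model positions.  Widths are tied by default
as `σ_i = w · spacing_i`, where `spacing_i` is the local inter-peak distance
(central difference; one-sided at the ends) and `w ∈ [10⁻³, 1]` is a single
fitted factor.  Peak widths in real gradients shrink along with peak
spacing, and the tied parameterisation keeps the compressed high-n region
identifiable where independent widths would not be; an independent-width
mode (`shared_width=False`) exists for well-resolved traces.  Fitting is
bounded trust-region least squares (`scipy.optimize.least_squares`,
`x_scale="jac"`, tolerances 10⁻¹⁰, max 5000 evaluations) over
`{s_i ≥ 0, w, A ≥ 0, k > 0, m, c}`.  Initialisation: `s_i` from the
trapezoidal signal mass within ± half a spacing of each centre (above the
5th-percentile baseline), `w = 0.25`, `A` from the first sample, `k` from
the distance to the first peak, `m = 0`, `c` at the 5th percentile.

On noise-free synthetic traces generated from the same family the fit is a
round trip and recovers scales to ~10⁻¹⁰ relative; at noise of 1% of the
maximum signal, scales of peaks carrying ≳ 3–4% of total mass are recovered
within a few percent.  Relative accuracy for a given peak degrades in
proportion to noise over peak mass — a peak holding a fraction of a percent
of the signal is simply not measurable to 5% at that noise level, which is a
statistical limit, not an optimizer property.

Normalized scales `v_i = s_i/Σs_j` are the peak-volume vector (the area
under an unscaled normal PDF is one, so `s_i` *is* the area of peak i).
Background components never enter volumes.  The P/M ratio is
`Σ_{n≥2} v_n / v_1`, with subunit peaks excluded from both terms.

## From counts to a modelled profile

Cell presets (all fields overridable):

| preset | total mRNA | total ribosomes | active | split | small-subunit mass |
|--------|-----------:|----------------:|-------:|------:|-------------------:|
| yeast  | 60 000     | 200 000         | 0.85   | 0.3   | 0.35               |
| hek293 | 300 000    | 2 000 000       | 0.85   | 0.6   | 0.37               |

The yeast constants are literature estimates for fast growth in rich medium.
For HEK293 the split fraction reflects the visibly larger free-subunit peaks
of mammalian gradients and the active fraction is carried over from yeast;
both should be treated as tunable rather than measured.

Genes with footprints but zero RNA counts would have infinite density; they
are excluded and reported in the QC summary, and footprint normalisation
runs over the retained genes so that the active ribosome pool is conserved
exactly across assigned peaks (Σ n-some masses + peak-0 mass =
`total_ribosomes · active_fraction` to machine precision).  Densities above
the physical packing cap of one ribosome per 10 codons (length/30 nt) are
*not* truncated — the over-cap fraction is itself a data-quality readout.
Densities between 0 and 1 follow the same straddling rule with floor 0; the
peak-0 share represents ribosome-free transcript mass and is dropped from
the profile (no ribosomal RNA, no OD₂₅₄ signal).  Mass landing above `n_max`
(default 20) pools into the `n_max` peak and the pooled amount is logged.

Rendering places a Gaussian of area `v_i` at each predicted position with
`σ_i = width_factor × local spacing` (default `width_factor = 0.2`), on a
grid spanning all peaks ± 4σ — ± 3σ would clip 0.27% of each peak's area,
while ± 4σ keeps the rendered trace area within ~10⁻⁴ of one.

## RMSD, the null, and clustering

RMSD between normalized volume vectors is computed over the union of peak
indices (absent peaks read as zero; inputs must sum to 1 within 10⁻⁶).  The
null is a normal fitted by maximum likelihood (sample mean and sd, ddof 0)
to all C(n,2) pairwise RMSDs of a known-good collection; a collection of
identical vectors has zero variance and is rejected as degenerate.  The
P-value is the plain upper-tail probability P(X ≥ RMSD): large RMSD ⇒ small
P, values below the null mean give P > 0.5 and are reported unclipped.
Clustering is complete-linkage agglomerative on union-aligned vectors with
Euclidean distance; candidate cluster numbers are scored with the standard
Davies–Bouldin index and the minimum is chosen (a `max-inverse-db` mode
maximizes the inverted between/within ratio, which selects the same k; the
index is sometimes described in its inverted form).  Note that on
unstructured data DB scores fluctuate non-monotonically with k — the score
separates real structure from its absence but does not rank k smoothly.
Meta-profiles are per-cluster means of aligned vectors, renormalized.

## The synthetic generator

`FixtureSpec` emulates a fast-growing yeast cell: ~60 000 mRNA copies;
log-normal per-gene densities (log-mean ln 2, log-sd 0.6, truncated at the
packing cap) giving profiles peaking near the tri-some; log-normal copy
numbers (log-mean ln 5, log-sd 1.0) and CDS lengths (median 1.2 kb, floored
at 300 nt); multinomial read sampling so library totals are exact and
conservation tests are sharp.  Expected footprint reads are proportional to
bound ribosomes (copies × density) — footprint counts scale with ribosome
numbers, not with gene length — and expected RNA reads to copies × length
(the inverse of the RPK transform).  The generator derives
`total_ribosomes` from the generated truth (Σ copies·density / active
fraction) so the downstream normalisation reproduces the generating
densities in expectation; with an inconsistent ribosome total every density
would scale by a constant, which is a feature of the real method (it is how
miscalibrated cell constants show up) but would make parameter-recovery
tests meaningless.  Trace backgrounds default to a debris peak a few times
the monosome height and a gentle upward baseline, matching the proportions
of real gradient scans.

What the generator does **not** emulate: UTR/isoform structure, positional
footprint bias within transcripts, library-preparation sequence biases,
overdispersed (non-multinomial) count noise, and detector artefacts other
than white noise.  Passing tests therefore demonstrate correctness of the
computational pipeline under idealised sampling, not robustness to every
failure mode of real libraries — the comparison machinery is precisely the
tool meant to surface those.

The packaged known-good collection (for out-of-the-box P-values) is a
deterministic synthetic stand-in: 31 multiplicative perturbations
(log-sd 0.05) of one yeast-like base vector from a fixed internal seed.  For
serious work, fit the null to your own curated collection with `null-fit`.

## Problem sizes

Routine tests use 400–2000 genes at 10⁵–10⁷ reads and 1200-point traces;
the high-depth limit checks use 10⁸ multinomial reads.  The full suite runs
in a few seconds on one core.

## Known limitations

- Auto-indexing of detected peaks assumes the first post-cutoff peak is the
  monosome and that no intermediate peaks are missed; noisy traces need
  explicit indices or a smoothed trace.
- The fitted-normal null is a convenience model; pairwise RMSDs are bounded
  below by zero and mildly right-skewed, so extreme-tail P-values are
  approximate.
- No isoform awareness: one length per gene, shared by RNA and footprint
  normalisation.
- The 80S/2-some shoulder is not deconvolved beyond what fixed-centre
  Gaussians provide; no spline baselines.
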