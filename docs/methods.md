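# Methods

## The spatial null model

The model asks: if two FISH-probed chromatin segments had no preference
for each other, how often would their signals touch by chance?

A nucleus is modelled as a flat ellipse with semi-axes *a* × *b* (µm).
Flow-sorted differentiated leaf nuclei are strongly flattened and FISH
signals are evaluated as projected round areas, so a 2D model is the
default; it also keeps the deterministic oracle tractable.  Each signal
is a disc of radius *r*; two signals are **associated** when their discs
touch or overlap, i.e. centre distance ≤ 2*r* (touching counts — the
criterion is attachment *or* overlap).

Placement depends on the genomic relation of the pair:

* **trans** (different chromosomes): both centres independent and
  uniform over the ellipse.
* **cis** (different arms of one chromosome): the centromere holds the
  two arm territories together, so both centres are drawn uniformly
  inside a single territory disc of radius *R<sub>t</sub>* whose centre
  is itself placed uniformly over the nucleus.  Concentrating both
  signals in one territory is what makes the cis expectation exceed the
  trans one.
* **homologous**: one centre in each of two independently placed
  territory discs.

Uniform sampling in the ellipse uses rejection from the bounding
rectangle (documented so independent implementations match
distributionally); uniform sampling in a disc uses the polar
square-root method.  Territory centres are drawn from the shrunken
ellipse with semi-axes (*a* − *R<sub>t</sub>*, *b* − *R<sub>t</sub>*).
This keeps the disc inside the nucleus along the axes exactly; between
the axes the inner parallel curve of an ellipse is slightly tighter
than the shrunken ellipse, so territories can protrude by a curvature
term of order *R<sub>t</sub>*²/*a*.  The simplification is absorbed by
calibration (below) and does not affect any packaged guarantee.

### Deterministic oracle

`analytic_trans_null` computes P(|X−Y| ≤ 2r) for independent uniform
points in the ellipse without Monte Carlo: the ellipse indicator is
rasterised on a dense grid (default 1024 pixels across, 4× supersampled
coverage fractions), its autocorrelation is taken by FFT — giving the
self-overlap area at every shift **v** — and the overlap is integrated
over |**v**| ≤ 2r with a one-pixel linear edge smoothing.  Against the
closed-form inter-point-distance CDF of the disc the error is below
5×10⁻⁶ at the default resolution, far below the Monte-Carlo standard
error at 10⁵ trials, so 3-SE agreement tests are meaningful.

### Geometry defaults and calibration

The study this model serves publishes its 2C random expectations (17.2%
cis, 9.9% trans) but not the geometry that produced them.  The package
therefore treats the constants as **calibration anchors, not emergent
predictions**:

| parameter | default | rationale |
| --- | --- | --- |
| nucleus semi-axes | 4.0 × 2.5 µm | typical flattened 2C leaf-nucleus footprint; a convention, configurable |
| territory radius *R<sub>t</sub>* | 1.5 µm | a chromosome-arm territory covering ~22% of the nucleus area; convention |
| signal radius (trans) | 0.5388 µm | calibrated so the 2C trans null = 9.9% |
| signal radius (cis) | 0.3470 µm | calibrated so the 2C cis null = 17.2% |
| trials per estimate | 10⁵ | SE ≈ 0.1 percentage points near p = 0.1 |

`calibrate_signal_radius` bisects on *r* using `estimate_null` with a
fixed seed (default 5×10⁵ trials per evaluation).  Because the seed is
fixed, the sampled centre distances are identical at every radius, the
estimated percent is exactly non-decreasing in *r*, and bisection
converges; default tolerance 0.2 percentage points.  The per-relation
radii reflect that cis and trans expectations cannot both be hit with a
single radius on one fixed territory geometry; the calibrated defaults
are packaged as constants and re-derived in the test suite.

## Frequency scoring

Input is a TSV with one row per nucleus × probe × homologue:
`nucleus_id, ploidy, tissue, probe_id, homolog_index, signal_count,
positions, flags`, where `positions` holds `x;y` pairs separated by `|`
(µm, image frame — no registration between nuclei) and `flags` is a
comma-separated subset of `associated_with:<probe>`, `cohesive`,
`separated_from_adjacent`, `outside_CT`, `elongated`.

Conventions, chosen where the source conventions are implicit:

* **Association** is counted per nucleus; *n* = nuclei in which both
  probes were scored.  A recorded `associated_with` flag is a positive
  call and takes precedence; in positional mode any signal of one probe
  within the distance threshold (default: the signal diameter 2*r* of
  the model geometry) of any signal of the other also counts.  Rows
  without flags are valid negative calls.
* **Elongation**: total signal count of the probe exceeds the ploidy
  threshold (>2 in 2C, >4 in 4C; for higher endopolyploid classes the
  ploidy-level signal number, a convention beyond the source data), or
  the `elongated` flag.  Mixed-ploidy input is rejected rather than
  silently pooled.
* **Cohesion** is scored per homologue in 4C+ nuclei: cohesive when the
  sister signals appear fused (`signal_count == 1`).  2C input raises
  an error — there are no replicated sisters to score.
* **Separation** of adjacent probes is scored per matched (nucleus,
  homologue) record pair; in 4C tables per-chromatid denominators are
  obtained by entering one row per chromatid lineage.  An optional BED
  annotation gates the metric: the probes must overlap or abut.
* **Out-looping** needs the categorical `outside_CT` flag — a
  territory boundary cannot be derived from point positions.
* Percentages are displayed rounded half-up to one decimal (the
  reporting convention); all comparisons use full precision.

## Exact tests

An observed summary (k of n) is compared with a null percentage by
building `[[k, n−k], [k₀, n−k₀]]` with k₀ = round(null·n/100) — the
expected count at the observed sample size, mirroring a comparison of
two equally sized samples — and applying the two-sided Fisher's exact
test (sum of hypergeometric point probabilities ≤ that of the observed
table).  How a simulated proportion becomes the second sample is a
genuine design choice; the alternative, an exact binomial test against
the fixed null proportion, is exposed via `method="binomial"` and is
the less conservative of the two.  Expected counts round half-up for
determinism.  No multiple-testing correction is applied: stars are
per-comparison annotations (strict inequalities at 0.05/0.01/0.001).
Empirically the Fisher construction stars well under 6% of populations
generated at the null rate (n = 150), as the acceptance run recomputes.

## Co-expression

"Mean-normalised" intensities are interpreted gene-wise: each value is
divided by the gene's across-sample mean and log2-transformed, so 0
means the gene's average level.  Spearman's rs uses average ranks on
ties; on untied data the rank-difference form 1 − 6Σd²/(n(n²−1)) is
used so monotone sequences give ±1 exactly.  P-values are two-sided
throughout (sidedness being another source-implicit choice): for n ≤ 9
the exact permutation distribution of untied ranks is enumerated (9! =
362 880 permutations, cached per n); for larger n the t approximation
t = rs·√((n−2)/(1−rs²)) on n−2 df, returning the smallest positive
float at |rs| = 1.  The two branches agree within 0.02 at the
cross-over.  High/low co-expression defaults (rs ≥ 0.7 high, |rs| ≤
0.3 low) are explicit conventions, overridable.  Genes to exclude
(e.g. ids with splice variants that a given database cannot accept)
are handled by the caller via the candidate lists, not hard-coded.

## Synthetic data

`gen_nuclei_population` emulates a flow-sorted leaf-nucleus FISH
experiment with one scored homologue pair per nucleus.  With
probability `p_assoc` the pair is *forced* to associate: the first
signal is placed by the null model, the second uniformly within the
association threshold of the first (clipped to the nucleus) — the
simplest mechanism with the right marginal.  Otherwise both signals are
placed by the null model of the configured relation, so the baseline
association rate equals the model's random expectation; with the
point-signal geometry (`point_signal_config`, r = 0.01 µm) that
baseline is negligible and `p_assoc` is the sole association source,
the setting used for parameter-recovery checks.  Cohesion, elongation
and out-looping are independent Bernoulli draws encoded in flags and
signal counts (correlated configurations, e.g. cohesion–elongation
interplay, are not modelled).  Defaults mirror the study scale: 200
nuclei, p_assoc = 0.135, p_elongation = 0.24, p_cohesion = 0.581 (4C),
p_outloop = 1/300.

What the generator does *not* emulate: optical blur and segmentation
error, partially associated configurations, correlated flags, homolog
mis-assignment, and any spatial structure beyond the territory discs.
Passing recovery tests therefore show the *calculators* are correct
under the stated sampling model, not that real microscopy data meet
that model.

`gen_expression_matrix` draws each block's log-intensities as
loading·z + noise with a shared per-sample factor z; the loading is
scaled against the noise so the within-block Pearson correlation of
log-intensities equals `latent_correlation` ρ exactly, giving an
implied rank correlation (6/π)·asin(ρ/2) (= 1 when noise_sd = 0).
Values are log-normal, hence positive, as microarray intensities must
be.  Off-block genes are independent.

## Numerical and degenerate-input choices

* One seedable `numpy` Generator per operation; identical seeds give
  byte-identical outputs (tables, estimates, reports).
* Radius calibration raises if the target is unreachable at the maximal
  admissible radius (signal ≤ territory ≤ semi-minor axis).
* `estimate_null` with 0 trials, constant sequences in `spearman_rs`,
  empty segment maps, inverted thresholds, negative contingency counts
  and unknown ploidy labels all raise typed errors rather than
  returning NaN.
* An all-zero territory-centre domain (territory radius = semi-minor
  axis) degenerates gracefully to the major-axis segment.
* Output files carry `# nucassoc <version>`, a 12-hex config hash
  (excluding the output path) and the seed, so a report identifies the
  run that made it.

## Problem sizes in the packaged checks

Acceptance-level checks use 10⁵-trial null estimates, 100 seeds × 500
nuclei for recovery coverage, 1000 replicates × 150 nuclei for the
empirical test size, and 500-sample expression matrices for rank
correlation recovery — sizes at which the binomial standard errors are
small against the tested tolerances while a full run stays fast on one
CPU.

## Known limitations

* The model is 2D; a 3D ellipsoid mode could sit behind the same
  interface but is not implemented.
* Heterochromatic chromocenters, nucleolus-associated positioning and
  radial preferences are not modelled; the territory disc is the only
  spatial constraint.
* The published 2C constants are anchors by construction — the model
  cannot independently predict them, and no constants are published for
  4C or higher classes (requesting them raises).
* Partial association (visually intermediate configurations) is not
  represented; calls are binary.
* The biological frequencies quoted in the documentation (13.5%, 24.0%,
  58.1%, …) come from microscopy data that are not publicly archived;
  the package covers them as worked examples exercising the frequency
  arithmetic, not as reproducible results.
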