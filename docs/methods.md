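# Methods

## Background

Capture-C profiles all cis ligation partners of selected restriction
fragments ("viewpoints" or capture probes) at restriction-fragment
resolution.  Because random re-ligation frequency falls steeply with
genomic distance, calling a true interaction means asking whether the
observed junction count at a given distance exceeds what random collisions
would produce there.  `capcall` implements that test as a three-stage
model: normalization, a distance-decay/dispersion null, and sliding-window
significance, followed by a likelihood-ratio test for differences between
conditions or cell lines.

## Normalization and binning

The raw junction count Y_{x,j} between fragment x and probe j is
normalized to the probe's total captured interactions Y_j and the fragment
width W_x:

    Ybar_{x,j} = Y_{x,j} / (Y_j · W_x) · NF,       NF = 1e8.

NF only sets a convenient common scale; with the default synthetic library
size (4×10^5 junctions per probe) normalized bin values land numerically
near raw bin counts.  Profiles are summed into 2-kb bins by fragment
midpoint (half-open bins, boundary midpoints assigned upward).  Bin 1
starts at the edge of the 2-kb exclusion zone on each side of the
viewpoint; the left and right arms share the distance index i, since the
model describes distance, not direction.  The exclusion zone removes the
short range dominated by undigested self-circles, which the read-pair QC
(below) shows are confined to spans under ~2 kb.

Three families of DESeq-style median-of-ratio factors remove residual
scale differences:

* **C_e (experiment)** — per bin, the geometric mean of the experiment's
  profile across probes is compared with a geometric reference across the
  experiments of the cell line; C_e is the median ratio over bins.  The
  reference is geometric on both sides deliberately: comparing a geometric
  numerator against the arithmetic pooled curve would carry a shared
  Jensen-inequality bias (≈ 4% under the default overdispersion), which
  both breaks the identity C_e = 1 for identical experiments and
  measurably inflates the null tail of the window test.  With the
  geometric reference both properties hold exactly/within noise.
* **C_j (probe)** — the probe's geometric mean over bins relative to the
  experiment-wide geometric mean, median over experiments, computed within
  each cell line.  Probe-normalized window counts are Xbar = Ybar / C_j.
* **C_cl (cell line)** — the probe-level geometric mean within one cell
  line relative to all cell lines, median over probes; applied as
  XCbar = Xbar / C_cl before cross-cell-line differential tests.

Geometric means use strictly positive values only (the DESeq convention);
the number of masked zero bins is recorded in the run manifest.

## The null model

The expected normalized count at distance d (in 2-kb bin units, d_i = i)
follows a power law fitted on log–log axes:

    mu_i = intercept · d_i^(−delta),       intercept = e^{k_decay} − 1.

Expressing distance in bin units makes the intercept exactly the expected
signal in the first bin beyond the exclusion zone.  The fit is ordinary
least squares of log E[Ybar_i] on log d_i — the maximum-likelihood estimate
under log-normal errors — and requires at least five positive bins spanning
a decade of distance.  A window at genomic distance D maps to
d = (D − exclusion)/bin_width + 1/2, so bin midpoints land on integers.

Counts at a given distance are treated as negative binomial with variance
beta_i·mu_i.  Rather than a fixed dispersion, beta is a linear function of
the mean:

    beta_i = alpha · mu_i + k_disp,   clamped to >= 1 at prediction time.

(alpha, k_disp) maximize the NB likelihood of all (probe, experiment, arm,
bin) observations, with per-observation mean C_e·mu_i, via a coarse-grid
multistart (alpha ∈ {0, .01, .05, .2} × k ∈ {1, 2, 5, 20}) polished by
L-BFGS-B, convergence 1e-8 on the log-likelihood; the optimization is
deterministic.  The constant-dispersion model is the alpha = 0 special
case; if the fitted variance nowhere exceeds the mean the model falls back
to Poisson with a warning.  The NB is parameterized throughout by its
moments: size r = mu/(beta−1) and success probability 1/beta.

Two historically colliding symbols are disambiguated as `k_decay` (decay
intercept exponent) and `k_disp` (dispersion intercept).

## Window testing and stratified FDR

Overlapping 2-kb windows stepped every 200 bp tile both arms beyond the
exclusion zone.  A window's value is the sum of fragment-level Ybar over
fragments whose midpoint falls inside, divided by C_j.  Its p-value is the
NB upper tail P(Y > floor(Xbar)) at mean C_e·mu(d) (scaled proportionally
if window width ≠ bin width) and dispersion beta(mu).  Flooring the
continuous normalized count before the discrete tail is conservative —
it can only raise the p-value.  Windows beyond the fitted distance domain
are scored with the extrapolated mean and flagged.

Because the achievable p-values differ sharply across distance (near bins
have large means, far bins small ones), Benjamini–Hochberg is applied
separately within distance strata — the 2-kb bin index, pooled across
probes and replicates.  Strata with fewer than 50 tests (configurable) are
merged with the next stratum outward, since BH in tiny strata is unstable.
Runs of overlapping or abutting significant windows (default q <= 0.05;
the threshold is a package default, configurable) are merged into maximal
regions whose p and q are the minimum over member windows.  Replicates are
tested separately; a region is carried forward if significant in any
replicate.

## Differential testing

Significant regions from all conditions and replicates are merged into a
union set; each union region carries region-level counts (the sum of
fragment-level Xbar inside the region, not window sums, avoiding
double-counting from overlap) from every experiment, including those where
the region was not itself significant.  The null NB-GLM fits one shared
mean; the alternative fits a mean per condition; both use the fixed
dispersion law beta(mu) from the background fit, because two replicates
per condition cannot identify a free dispersion.  The statistic
2·(ll_alt − ll_null) is referred to chi-squared with 1 df, and p-values
are BH-adjusted across regions (unstratified).  Counts enter the GLM
floored to integers (configurable to round-half-even); means are fitted by
bounded 1-D optimization on log(mu), so the statistic is non-negative and
invariant to condition labels.  Fold difference is the ratio of fitted
condition means.  Cross-cell-line tests use XCbar counts, which makes the
test invariant to a global depth difference between cell lines.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, on
one synthetic chromosome:

* **Fragment grid** — recognition sites (GATC) planted at quasi-regular
  spacing, uniform on mean·(1 ± 0.25) with mean 256 bp.  A matching DNA
  sequence (sites at boundaries, motif-free filler) can be emitted for
  digestion tests.
* **Decay** — proximal fragment means follow
  depth_e · eff_j · intercept · d^(−delta), with d in bin units, scaled by
  fragment width within a bin.
* **Overdispersion** — the law var = (alpha·mu + k_disp)·mu is specified
  at the 2-kb aggregation scale the model is fitted at: each fragment is
  drawn NB with the bin-scale dispersion at its distance, so the sum over
  any 2-kb window obeys the law on the normalized scale (a per-fragment
  dispersion law would be diluted by a factor of the fragments-per-bin
  count when aggregated, making the generator's parameters unrecoverable
  by the model that analyzes it).
* **Library size and probe efficiency** — each probe's total is pinned to
  depth_e · 4×10^5 junctions; probe efficiency multiplies only the
  proximal (within-span) signal and the remaining mass is placed as flat
  distal cis background.  Total-count normalization cancels any factor
  that scales a probe's whole library, so this is exactly the construction
  under which capture-efficiency differences survive normalization as
  proximal-yield differences — the residual effect C_j exists to remove.
  An optional per-experiment yield (and log-normal replicate jitter) plays
  the same role for C_e.
* **Spikes** — true interactions multiply the decay mean over a chosen
  window, per condition if requested; the truth table records them for
  recovery tests.
* **Read pairs** — random re-ligations draw the four strand combinations
  equiprobably (same : inward : outward = 2 : 1 : 1); self-circles are all
  outward with spans below a cutoff (default 2 kb).

Defaults (chosen once as the package's study conditions): 3-Mb chromosome,
4 viewpoints, ±250-kb analysis span (most Capture-C interactions lie
within 250 kb), 2-kb exclusion, delta = 1, intercept = 6000 expected
junctions in bin 1, alpha = 0.05, k_disp = 2, 4×10^5 junctions per probe.
The library total is matched to NF/mean-width so normalized counts sit on
the raw-count scale, which keeps k_disp numerically comparable between the
generative and fitted scales.

What the generator does **not** emulate: mappability variation, GC bias,
trans contacts, domain structure (TADs) superimposed on the decay,
fragment-level cutting-efficiency heterogeneity, and realistic
heavy-tailed fragment-size distributions.  On a real digest, fragment
widths are roughly geometric; dividing by W_x then makes 1/W heavy-tailed
and adds width noise that the quasi-regular synthetic grid deliberately
suppresses.  Passing the calibration tests therefore demonstrates the
correctness of the statistical machinery under the model's own
assumptions, not robustness to these real-data features.

## Numerical choices and edge cases

* NB draws and tails fall back to Poisson when beta <= 1 (+1e-9).
* Fragment midpoints on a bin or window boundary go to the
  higher-coordinate side (half-open intervals everywhere; 0-based BED
  coordinates in all output).
* Viewpoint anchors are the capture-fragment midpoint; supplied positions
  snap to the midpoint of the containing fragment.
* Trans junctions are dropped at ingestion with a logged count; the
  analysis is cis-only.
* Probes with zero total counts are dropped from normalization with a
  warning; all-zero experiments are an error.
* The LRT clamps tiny means at 1e-8 so all-zero conditions remain finite.

## Verification

The test suite checks each stage against independent oracles: hand-scanned
digests, direct evaluation of the normalization formula, brute-force pmf
summation for the NB tail (1e-10 over mu <= 50, beta <= 10, x <= 200), a
textbook step-up BH implementation for both FDR stages, moment checks and
parameter-recovery runs against the generator's truth, uniformity of null
window p-values (KS < 0.02 at ~1e5 windows), type-I error of the null LRT
(0.05 ± 0.015 at 2000 regions), and realized FDP <= 0.10 with >= 90%
recovery of 5-fold spikes within 100 kb on a 95/5 null/spiked mixture over
20 seeds.  Problem sizes (one 3-Mb chromosome, 4 probes, 2–10 replicates)
were chosen so the whole suite verifies the pipeline at desk scale.
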