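# Methods

This note documents the models, parameter choices and numerical decisions
behind `regulonscan`, and what the synthetic-data tests do and do not show
about real data.

## Information-theoretic site models

An aligned set of n equal-length sites yields positional frequencies
f(b, l) = (count(b, l) + pc) / (n + 4·pc) with pseudocount pc (default 0).
Per-column information is 2 − H(l) − e(n) bits, H the Shannon entropy of
the column; summed over a column range this is the total information
R_sequence.  Individual information of a sequence is
Ri = Σ_l Riw(seq[l], l) with Riw(b, l) = 2 + log2 f(b, l) − e(n), so the
mean Ri over the alignment's own members equals R_sequence (asserted to
1e−6 in the tests when pc = 0).

**Small-sample correction e(n).**  The plug-in entropy of a column
estimated from n bases is biased low; for an equiprobable 4-letter
background the default correction is the first-order approximation
e(n) = 3 / (2 ln2 · n) bits per column.  An exact-enumeration estimator
(expectation of the plug-in entropy over all multinomial base-count
compositions at p = 1/4) is available via
`small_sample_correction(n, "exact")` and is preferable for n ≲ 12, where
the approximation is weakest.  Both conventions for Riw are implemented —
with e(n) subtracted per position (default) or applied only to the total —
because published bit values differ between toolchains; the default keeps
the identity between mean Ri and R_sequence exact.

**Sampling SD of R_sequence.**  Reported as the delta-method standard
deviation of the plug-in entropy sum: var_l = [Σ_b f (log2 f)² − H_l²]/n,
sd = sqrt(Σ_l var_l).  This is an analytic approximation, not a bootstrap;
for a fully conserved column it is exactly 0.

**Zero frequencies.**  With pc = 0 an unseen base has weight −∞; scanning
treats such windows as below any finite cutoff.  This preserves the
"never observed" semantics of a 0-bit theoretical binding limit while
avoiding NaNs.

**Scanning conventions.**  Coordinates are 0-based half-open on the
forward strand.  Reverse-strand windows are scored as their reverse
complement; when the same interval passes on both strands the higher-Ri
strand is reported ('+' on a palindromic tie).  `localbest` keeps the
highest-Ri call within a window (default 200 bp, start-to-start), ties
broken leftmost then forward strand — the tie-break is a package decision,
as is the strict "< window" conflict rule.

## Direct-repeat architecture

The 18-bp box alignment must extend to motif position +17 (21 columns)
because the second half-site frame (+8..+17) reaches 3 bp past the core;
the two 10-mers of each box are pooled (2n half-sites) into the single-DR
matrix.  Center-to-center (ctc) spacing is operationalized as
start-to-start distance of the 10-bp elements, identical to true
center-to-center for equal lengths.  Flanks are rescanned in a 100-bp
window centered on the box at a 0-bit cutoff; overlapping opposite-strand
hits at one locus resolve to the higher-Ri strand, and classification uses
anchor-strand elements only (both strands are recorded).

Classification walks the ordered spacing chain: 11 bp (one helical turn)
continues a consecutive run, a final 22-bp spacing labels the site
`+distal`, any other spacing breaks the canonical chain (`+offspaced`;
the extra element is recorded but excluded from n_dr).  The spacing
tolerance defaults to 0 bp — a 12-bp spacing is a violation, consistent
with footprinting evidence that one extra base pair abolishes protection
of the distal repeat — and is configurable.

## ChIP-chip analysis

Quantile normalization replaces each track's sorted values with rank-wise
means across tracks (ties averaged).  It is idempotent on tie-free data;
with ties the tie-averaging step perturbs the pooled reference slightly,
so exact idempotence holds only from the second pass on.

Region calling is a documented stand-in for the external percentile-based
tool it emulates: probes strictly above the track-wide percentile
threshold (95th or 98th), runs of at least `min_run_probes` (default 4)
probes become regions, and each region carries a binomial-null run
p-value p0^len with p0 = 1 − percentile/100.  Replicate intersection keeps
connected components of the cross-replicate coverage intersection,
expanded to the union of contributing regions, with support flags.

Filters only ever add flags; coordinates are never altered.  The
RNAP-crosslink filter bins the genome (300 bp), takes per-bin maxima,
computes Pearson r and a least-squares regression of regulator on RNAP
signal over bins with RNAP log2 ≥ 1.75, and flags a region when (i) it
overlaps at least one such bin, (ii) every overlapping high-RNAP bin has
condition-independent regulator signal (aerobic and anaerobic maxima
within 0.8 of each other), and (iii) no binding-site call of ≥ 10 bits
lies inside the region.  The conjunction and its two free constants (0.8,
10 bits) are a parameterized surrogate for a phenomenon the source data
only illustrate; with fewer than 3 qualifying bins the correlation is
undefined and nothing is flagged.

## ChIP-seq deconvolution

The model: per-bp strand counts are Poisson with rate
λ_s(x) = bg_s(x) + Σ_j a_j k(x − (p_j ∓ d/2)), where k is a unit-mass
Gaussian kernel (bandwidth 30 bp, truncated at 4 SD for the fit), d is
the fragment offset learned as the argmax of the fwd/rev density
cross-correlation, a_j is the per-strand read amplitude of source j, and
the background is the input kernel density divided by the depth-correction
factor (input reads / IP reads), taken elementwise-max with a broad local
rate and the global input rate.  The multi-scale background matters: a
sparse input's kernel density dips toward zero between reads, where a
handful of IP reads would otherwise score unbounded likelihood gains.

Fitting is deterministic: (1) greedy placement at the matched-filter
argmax, amplitude by Newton iteration on the local Poisson likelihood,
down to a low gain floor; (2) coordinate-descent refinement of every
source's position (±2 bandwidths, coarse-then-fine grid) and amplitude;
(3) split moves — replacing one source by a refined pair is accepted only
if it improves the joint log-likelihood by `llr_threshold` (default
21.75), the same price any extra source pays; (4) a removal test — a
source survives only if deleting it, after letting the remaining sources
re-settle, costs at least `llr_threshold`.  The reported per-call LLR is
that removal cost.  The split/prune pair is what separates two sources a
fraction of a fragment length apart: a single midpoint kernel mis-models
the bimodal strand densities by tens of log-likelihood units at ~100
reads per source, which is exactly the margin the threshold tests.

Edge convention: tracks are padded so every kernel window is full-length;
padding carries zero reads and a floor rate, so sources near sequence
ends pay for kernel mass falling off the genome.

Measured on the simulation conditions used throughout (fragment
150 ± 20 bp, ~100 reads per source, uniform background 0.01 reads/bp,
6-kb window): two sources are resolved in ≥ 90% of seeds at 76 bp
separation but not at 66 bp, single sources localize within ±2 bp, pure
background yields no calls at the default threshold in ≥ 95% of seeds,
and the sample-swap FDR (swap calls / forward calls) tracks the realized
null call count within a factor of 2.

## Regulon integration

Sign convention: expression is measured as deletion strain over wild
type, so **up in the deletion = repressed by the regulator**.  A gene
passes at |log2FC| ≥ log2(2) and p < 0.05; a multi-gene operon is
differentially expressed when ≥ 2 member genes pass with consistent sign
(mixed signs veto the operon — operon transcription is unidirectional); a
single-gene operon passes on its own gene (configurable, since a
two-gene rule cannot apply to it).  Regions map to operons through a
strand-aware upstream window of 500 bp from the TSS (or first-gene start
when no TSS is annotated) — the window length is a package default, as no
standard value exists; divergent promoters map one region to both
operons, and intragenic regions map to none.  Differentially expressed,
unbound operons are classified indirect unless a ≥ 15-bit site (the box
model's average information) is found upstream by the motif scan, in
which case they stay in the undetermined bound/unbound margin
(`DE-not-bound`).  The transcription-factor hierarchy report is pure
bookkeeping over an external TF-target annotation; self-regulation rows
are excluded.

## Synthetic data: what it does and does not show

The generators produce exactly the structure the analyses assume — i.i.d.
background at a chosen GC, sites sampled from the model's own positional
frequencies (or consensus), reads at source ∓ F/2 with F ~ Normal(μ, σ),
probe plateaus plus Gaussian noise, clean operon-level expression effects.
Passing the plant-and-recover suites therefore demonstrates algorithmic
correctness (the code finds what its model says should be there), not
robustness to real-data pathologies: mappability artifacts, GC bias,
probe cross-hybridization, overdispersed expression noise and correlated
replicate structure are all out of scope and untested.  Default synthetic
conditions (noise SD 0.3 on arrays, 2.0 log2 planted effect, 100
reads/source, 0.01 reads/bp background) were chosen once as realistic
mid-range values for bacterial ChIP experiments and are fixed in the
planting records.

Problem sizes in the test and acceptance runs (6-kb deconvolution
windows, 40–120 kb array/genome simulations, 50 seeds per resolution
point) are the package's standard demonstration scales; all scale
linearly if enlarged.

## Known limitations

* The deconvolution is a greedy local optimizer with split/prune repair,
  not a global one; pathological many-source configurations can settle in
  local optima.
* The exact e(n) enumerator is O(n³) over compositions and intended for
  small n only.
* The RNAP-crosslink criterion is a surrogate with two free constants;
  on real data they should be examined against the deletion-strain
  control.
* Quantile normalization's tie handling is mean-assignment, which is the
  common convention but makes strict idempotence hold only for tie-free
  data.
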