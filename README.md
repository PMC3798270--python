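# regulonscan

Tools for mapping the regulon of a bacterial two-component response
regulator — the kind of global repressor/activator (ArcA-like, OmpR/PhoB
family) that binds chains of short direct repeats and silences dozens of
operons at once.  The package covers the full computational arc from an
aligned set of binding sites to a classified regulon:

* **Information-theoretic site models.** From an alignment of n sites the
  package builds a positional frequency matrix f(b, l) and the bit weights
  Riw(b, l) = 2 + log2 f(b, l) − e(n), where e(n) is the small-sample
  entropy correction.  Model strength is the total information
  R_sequence = Σ_l [2 − H(l) − e(n)] bits; a candidate site's strength is
  its individual information Ri = Σ_l Riw(seq[l], l).  Scanning reports
  every genome window above a bit cutoff on either strand, `localbest`
  keeps the best hit per window, and sequence walkers render per-base
  contributions.

* **Direct-repeat (DR) architecture.** The 18-bp core box is two 10-bp DR
  half-sites at 11-bp center-to-center spacing (one helical turn).  The
  two halves of every aligned box are pooled into a single-DR model, the
  flanks of each box are rescanned at a 0-bit cutoff (the theoretical
  lowest limit of binding), and each site is classified by its spacing
  chain: `2DR` … `5DR-consecutive`, `+distal` (a final 22-bp, two-turn
  spacing), `+offspaced` (any other spacing, recorded but excluded from
  the canonical count).

* **ChIP-chip region calling.** Quantile normalization across channels and
  replicate arrays, enriched regions as runs of probes above a track-wide
  percentile (95th/98th stringencies), replicate intersection, and two
  false-positive filters: overlap with a regulator-deletion control, and
  the RNAP-crosslinking artifact at highly transcribed loci (signal that
  tracks RNAP occupancy in 300-bp bins above a 1.75 log2 cutoff and does
  not change with growth condition).

* **ChIP-seq point-source deconvolution.** Strand-separated read 5' ends
  flank a binding point at about half the fragment length.  The caller
  learns that offset from the strand cross-correlation and fits point
  sources to the per-bp Poisson counts against a depth-corrected input
  background, with greedy placement, split and prune moves; every retained
  source must buy at least `llr_threshold` (default 21.75) in joint
  log-likelihood.  FDR is estimated by a sample swap (input-over-IP calls
  divided by IP-over-input calls).

* **Regulon integration.** Binding regions from both platforms are merged
  (single-support regions survive only when they contain a ≥10-bit site),
  operons are called differentially expressed (≥2-fold, p < 0.05, ≥2
  consistent genes per multi-gene operon), regions map to operons through
  strand-aware upstream windows, and each operon is classified
  direct-repressed / direct-activated / indirect / bound-not-DE, with
  promoter-overlap annotation against the TSS/−10/−35 elements.

* **Synthetic data.** Every input the pipeline consumes can be generated
  with known ground truth (planted sites and architectures, strand-offset
  reads, probe tracks, expression tables), emitted with a planting record
  that drives the test suite's oracle checks.

## Worked example

`examples/04_chipseq_deconvolution.py` plants two binding sources 76 bp
apart — much closer than a sequencing fragment length — and resolves them:

```
IP reads: 259, input reads: 138
estimated fragment offset: 161 bp
true sources: (2962, 3038)
  call at 2964 bp  LLR 34.4  amplitude 46 reads/strand
  call at 3032 bp  LLR 34.4  amplitude 54 reads/strand
sample-swap FDR: 0.0
```

The offset (~161 bp) recovers the simulated fragment length (150 ± 20);
the two calls land within a few bp of the true sources, each worth ~34
log-likelihood units (well above the 21.75 acceptance bar); the swapped
run makes no calls, so the empirical FDR is 0.  The other examples walk
through the motif model (`01`), DR architecture census (`02`), array
region calling with the RNAP-artifact filter (`03`) and regulon
classification (`05`), each printing the numbers it computes.

A thin CLI wraps the same stages
(`regulonscan simulate | build-pwm | scan | architecture | chip-array |
chip-seq | integrate | all`); every stage writes a manifest with a config
hash so a run is reproducible from its output directory.

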