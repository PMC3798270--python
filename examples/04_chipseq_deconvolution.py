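"""Resolve two closely spaced binding sources from strand-separated reads.

Read 5' ends flank a binding point at about half the fragment length on
either side.  The deconvolution learns that offset from the strand
cross-correlation, then fits point sources by greedy Poisson placement
with split/prune moves, each source paying a fixed log-likelihood-ratio
price.  Two sources only 76 bp apart — far closer than a fragment length —
come out as two distinct calls, and a sample swap (input over IP) gives
the empirical false-discovery rate.
"""

from regulonscan import deconvolve, estimate_offset, sample_swap_fdr
from regulonscan.simulate import simulate_reads

L = 6_000
truth = (2_962, 3_038)  # 76 bp apart
ip, inp, _ = simulate_reads(
    L, list(truth), coverage=100, fragment_mu=150, fragment_sd=20,
    background_rate=0.01, seed=1,
)
print(f"IP reads: {ip.n_reads}, input reads: {inp.n_reads}")
print(f"estimated fragment offset: {estimate_offset(ip, genome_length=L)} bp")

calls = deconvolve(ip, inp, genome_length=L)
print(f"true sources: {truth}")
for c in calls:
    print(f"  call at {c.source_position} bp  "
          f"LLR {c.llr:.1f}  amplitude {c.amplitude:.0f} reads/strand")

swap = deconvolve(inp, ip, genome_length=L)
fdr = sample_swap_fdr(len(calls), len(swap))
print(f"sample-swap FDR: {fdr}")
# Expect two calls within a few bp of 2962 and 3038, each with LLR far
# above the 21.75 acceptance threshold, and FDR 0.0 (no swap calls).
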