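"""Measure spike-in recovery accuracy for one benchmark cell.

A benchmark cell fixes motif length n, defined positions d and spiked
occurrences N.  For each replicate a distinct motif is derived from the
(n, d) mask, spiked into its own 100-sequence set, and discovery must
rank it first.  Here: an easy cell (d = n, exact 6-mers, N = 20) against
a harder degenerate one (d = 3 of 6, N = 5).
"""

from motifsieve import generate_synthetic_proteome, spike_recovery_accuracy

background = generate_synthetic_proteome(500, (100, 500), seed=7)

for n, d, N in [(6, 6, 20), (6, 3, 5)]:
    accuracy = spike_recovery_accuracy(
        background, n=n, d=d, N=N, replicates=5, lengths=(6,), seed=11
    )
    print(f"n={n} d={d} N={N:>2}: top-1 recovery accuracy = {accuracy:.0%} "
          f"(5 replicates)")

print()
print("Recovery saturates for information-rich motifs spiked many times and")
print("collapses for sparse degenerate ones - the 'twilight zone' where true")
print("motifs are indistinguishable from chance patterns by enrichment alone.")
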