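# motifsieve

Ab-initio discovery of short degenerate linear motifs (SLiMs) in protein
sequences.  Linear motifs are short (3–12 residue) patterns — `P..P`-style
consensus sequences in which only a few positions are constrained — that
mediate protein–protein recognition, localization signals, cleavage and
modification sites.  Their brevity and degeneracy make them invisible to
alignment-based methods; `motifsieve` finds them by **exhaustive
enumeration** and **enrichment statistics** alone, with no prior model of
the motif's structure.

## Method

Given a query set of `q` protein sequences that is a subset of a
background set of `b` sequences (e.g. a proteome):

1. every unmasked window of length `n` (3 ≤ n ≤ 12) in the query is
   indexed, along with **all** of its degenerate forms — `w` wildcards
   placed in every combination among the `n−2` interior positions
   (`WC = C(n−2, w)` layouts per window), keeping the first and last
   positions defined and at least 3 defined positions overall;
2. patterns seen in fewer than 3 query sequences are discarded, as are
   degenerate patterns whose sequence count does not exceed their best
   single-step parent (one fewer wildcard) by at least 2 — a wildcard
   that adds at most one occurrence carries no information;
3. each retained pattern is counted in the background (sequence-level:
   a sequence counts once however many windows match), giving `l`;
4. overrepresentation of a pattern seen in `k` query sequences is scored
   by the cumulative hypergeometric tail

   ```
   p = Σ_{i=k}^{min(l,q)}  C(l,i) · C(b−l, q−i) / C(b,q)
   ```

   computed in log space, and adjusted for the wildcard-placement space
   with a Šidák-style correction `p_adj = 1 − (1 − p)^WC`;
5. all lengths are merged into a single list ranked by `p_adj`.

Because the background supplies the expected occurrence counts directly,
compositional structure of the sequence space (e.g. serine runs) is
accounted for without Markov models: a pattern frequent in the proteome
is frequent in `l` and scores accordingly.

A spike-in benchmark generator reproduces the standard evaluation
protocol: binary defined/wildcard masks for every `(n, d)` combination,
batches of unique motifs derived per mask, each spiked into `N` of 100
sequences (one occurrence at most per sequence, wildcard positions
re-randomized per insertion), and a top-1 accuracy report per
`(n, d, N)` cell.

## Worked example

`examples/discover_motifs.py` plants the degenerate motif `K.LW.R` into
10 of 60 query sequences drawn from a 300-sequence synthetic proteome
and runs discovery:

```
spiked motif: K.LW.R  (into 10 of 60 query sequences)
pattern      k   l    q    b  WC  p_raw      p_adj
K.LW.R      10  10   60  300   6  5.392e-08  3.235e-07
K.LW        11  13   60  300   2  5.170e-07  1.034e-06
LW.R        10  12   60  300   2  2.530e-06  5.059e-06
SY.D         7   9   60  300   2  2.436e-04  4.871e-04
E.LTL        5   5   60  300   3  2.789e-04  8.364e-04
```

The spiked pattern ranks first: it occurs in all 10 spiked query
sequences (`k=10`) and nowhere else in the background (`l=10`), an
imbalance with raw tail probability 5.4e-08; its two end-trimmed
sub-patterns follow.  `examples/score_a_motif.py` and
`examples/run_benchmark_cell.py` walk through the statistic itself and a
benchmark accuracy cell.

## Command line

```
motifsieve discover --query Q.fasta --background B.fasta \
    --lengths 3-10 --masks regions.bed --adjust sidak --out motifs.tsv
motifsieve scan --patterns patterns.txt --sequences S.fasta --out counts.tsv
motifsieve bench generate --config bench.yaml --seed 7 --out bench/
motifsieve bench evaluate --manifest bench/manifest.tsv --out report.tsv
```

Masked regions (disordered/homologous stretches, given as a BED-like TSV
in 0-based half-open coordinates, or as lowercase residues in the FASTA)
are excluded from every window: wildcards never match a masked residue.

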