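# Methods

## Model and assumptions

`motifsieve` treats motif discovery as an enrichment problem.  The unit
of evidence is the *sequence*, not the match: a pattern's occurrence
count in a set is the number of sequences containing at least one
unmasked matching window.  This makes the cumulative hypergeometric
distribution the exact null model when the query is an unbiased sample
of the background — `k` carriers among `q` sequences drawn without
replacement from `b` sequences of which `l` carry the pattern — and
guarantees `k ≤ min(l, q)` whenever the query is a subset of the
background, which the pipeline enforces (same ids, identical residues;
query mask bits are propagated to the background copies so a masked
query window can never out-count its background copy).

The score of a pattern depends only on `(k, l, q, b)` and on its
wildcard multiplicity — never on its residue composition or length
directly.  Compositional structure of real sequence space (biased amino
acid usage, low-complexity runs) enters through `l`: patterns that are
common for compositional reasons are common in the background and score
poorly without any explicit Markov model.

## Enumeration

All length-`n` windows (3 ≤ n ≤ 12) whose positions are all unmasked are
indexed; each emits every degenerate variant obtained by replacing
interior positions with wildcards, for `w = 0 … n−3` (first and last
positions stay defined, at least three positions defined overall), i.e.
`Σ_w C(n−2, w) = 2^(n−2) − 1` variants per window.  Two filters follow:

- **support**: patterns in fewer than 3 query sequences are dropped;
- **parent pruning**: a degenerate pattern is kept only if its sequence
  count exceeds the maximum count over its *generated* single-step
  parents (same layout with one wildcard re-specialized; "generated"
  means the parent arose from at least one query window) by **≥ 2**.
  The rationale: if widening a position to a wildcard gains at most one
  sequence, the wildcard explains nothing the parent did not.  Where the
  comparison should be against one designated parent or all parents was
  genuinely open; we compare against the maximum over all generated
  parents, the strictest reading.

Internally each defined-position layout is handled as a projection:
window residues at the layout's offsets are packed into base-21 integer
codes (20 residues + a sentinel for non-standard letters, which are
force-masked on input), so per-layout counting reduces to NumPy
sort/unique passes and the pruning rule to grouped maxima over parent
codes with one digit removed.  All combinatorial quantities
(`C(n−2, w)`, `20^d` spaces) use exact integer arithmetic — `20^12`
overflows 64-bit floats' integer range.

Counts produced this way are tested for exact equality against an
independent generate-and-scan oracle (plain string loops) on randomized
toy queries, and stored supports are re-derived by direct
window-matching.

## Scoring

The tail sum is accumulated in log space with `lgamma`-based binomial
coefficients and a max-shifted `fsum`; relative error against an exact
rational oracle is below 1e-10 for every admissible `(k, l, q, b)` with
`b ≤ 60` (tested exhaustively), and the boundary identities `k = 0 → 1`
and `q = b, k = l → 1` are returned exactly via the support floor
`k ≤ max(0, q + l − b)`.

The wildcard adjustment multiplies the effective number of hypotheses by
the placement count `WC = C(n−2, w)`.  The exact functional form used by
the original text output is not recoverable, so the package uses the
Šidák form `p_adj = 1 − (1 − p)^WC` (evaluated as
`-expm1(WC·log1p(-p))` for stability), which stays in `[p, 1]`; a
Bonferroni switch (`min(1, p·WC)`) is available for sensitivity
analysis.  No correction is applied *across* lengths: results for all
lengths are merged into one list ranked by `(p_adj, p_raw, w, pattern)`
— a deterministic total order.  Per-length ranking remains available by
calling `discover` with a single length (the CLI's `--lengths` accepts
single values, and `bench evaluate --lengths spiked` evaluates each
benchmark set at its own spiked length).

## Synthetic proteome and spike-in benchmark

The generator draws sequences of uniformly distributed length (default
100–500 residues) with i.i.d. residues from a yeast-like amino-acid
frequency table (configurable; the default sums to 1 after
normalization).  It emulates a real proteome's *length range and
first-order composition* only.  It deliberately does not reproduce
repeats, low-complexity regions, homologous families or domain
structure; consequently chance occurrence counts of short patterns are
*lower* and more Poisson-like than in a real proteome, and test results
transfer to real data only at the level of the statistic's behavior,
not of absolute accuracy numbers.

Benchmark construction: for each length `n` and defined-position count
`d = 3…n` a binary mask fixes the dimensionality (36 masks for lengths
3–10); each mask derives a batch of unique motifs by shuffling the
interior defined/wildcard layout per replicate and drawing defined
residues from the frequency table; each motif is spiked into `N` of its
set's 100 sequences.  Spiking overwrites a uniformly chosen window *in
place* (length-preserving) rather than inserting residues, so the
background's length distribution is untouched and the spiked query
remains a strict subset of the per-set background (spiked query plus
the unspiked remainder of the background pool).  Wildcard positions are
re-drawn at every insertion: the degenerate pattern, not a literal
string, is what is spiked.  Every set is a pure function of
(configuration, master seed); per-set seeds are SHA-256-derived from the
master seed and the set id, so any set can be regenerated independently
and manifest-only builds are cheap (the full 11,880-set manifest builds
in seconds; FASTA materialization is optional).

## Problem sizes used by the tests and the acceptance script

Exhaustive hypergeometric validation runs to `b = 60`; enumeration
equivalence uses 50 random 5-sequence queries (lengths ≤ 30, n ≤ 6);
recovery experiments use a 500-sequence synthetic background with
100-sequence query sets — 10 replicates at `(n=7, d=5, N=8)` over merged
lengths 3–10, and 20 replicates per occurrence level at `(n=5, d=3)`
evaluated at the spiked length.  These sizes were chosen as the smallest
at which the qualitative regimes (saturation for information-rich
motifs, collapse in the twilight zone) are visible.

## Known limitations

- **Query-to-background ratio drives separability.**  The spiked
  motif's raw P-value at full support is approximately `(q/b)^N`.  With
  a 500-sequence background (`q/b = 1/5`) and `N = 8` this is ~2e-6 —
  close enough to chance that two artifacts of exhaustive enumeration
  routinely overtake the true motif: (i) an *end-trimmed sub-pattern*
  (drop a defined terminal position) carries the same `k` and, in an
  i.i.d. background, often the same `l`, hence an identical raw P but a
  smaller `WC` and therefore a better adjusted P; (ii) some random
  pattern among the ~10^5 retained candidates beats 2e-6 by chance.
  With a proteome-scale background (`q/b = 1/30`) the spiked P drops to
  ~1.5e-12 while trimmed sub-patterns accrue several chance background
  occurrences, and recovery in the `d ≥ 5` regime approaches 100%.
  Measured at `(n=7, d=5, N=8)`, 10 replicates: top-1 accuracy is
  0.1–0.2 with a 500-sequence background and merged lengths 3–10,
  0.8 with either a 3000-sequence background or discovery restricted to
  the spiked length.  The parent-pruning rule cannot remove end-trimmed
  sub-patterns because they live at a different length.
- Occurrences are sequence-level by design; instance-level enrichment
  (multiple matches per sequence) is not modeled.
- No clustering or merging of overlapping/nested result patterns: the
  ranked list intentionally contains the full redundant family around a
  strong motif.
- Disorder prediction and homology masking are consumed as precomputed
  annotations, never computed.
- DNA alphabets, position-weight matrices and approximate/sampled
  enumeration are out of scope.
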