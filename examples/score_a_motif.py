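"""Score one motif's overrepresentation by hand.

Suppose a pattern occurs in k=8 of q=100 query sequences, and in l=12 of
b=3000 background sequences.  The cumulative hypergeometric tail gives
the chance of such an imbalance; the wildcard adjustment accounts for
the C(n-2, w) ways its wildcards could have been placed.
"""

from motifsieve import adjust_pvalue, hypergeometric_tail, wildcard_combinations

k, l, q, b = 8, 12, 100, 3000
n, w = 7, 2  # e.g. the pattern 'SF.H.TA'

p_raw = hypergeometric_tail(k, l, q, b)
wc = wildcard_combinations(n, w)
p_adj = adjust_pvalue(p_raw, n, w)

print(f"counts: k={k} of q={q} query, l={l} of b={b} background")
print(f"raw hypergeometric tail  P(K >= {k}) = {p_raw:.4e}")
print(f"wildcard placements      WC = C({n}-2, {w}) = {wc}")
print(f"adjusted P-value         1-(1-p)^WC = {p_adj:.4e}")
print()
print("Tiny values mean the motif is far more concentrated in the query")
print("than sampling alone would explain; a composition-matched but")
print("background-frequent pattern (larger l) would score far worse:")
for l_alt in (12, 50, 200):
    print(f"  l={l_alt:>4}: p_raw = {hypergeometric_tail(k, l_alt, q, b):.4e}")
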