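"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized code paths: plain
string loops, itertools enumeration and exact rational arithmetic.
"""

import itertools
from fractions import Fraction
from math import comb

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def oracle_match(pattern, residues, mask):
    """Window matching by direct loops; wildcards never match masked positions."""
    n = len(pattern)
    for i in range(len(residues) - n + 1):
        if any(mask[i:i + n]):
            continue
        if all(p == "." or p == residues[i + j] for j, p in enumerate(pattern)):
            return True
    return False


def oracle_generate_counts(seqs, n):
    """Generate-and-scan: every unmasked window emits all its degenerate
    variants; support is the set of emitting sequences (sequence-level).

    ``seqs`` is a list of (id, residues, mask) triples.  Returns
    pattern -> set of ids, over all generated patterns (count >= 1).
    """
    support = {}
    interior = list(range(1, n - 1))
    for sid, res, mask in seqs:
        for i in range(len(res) - n + 1):
            if any(mask[i:i + n]):
                continue
            kmer = res[i:i + n]
            for w in range(0, n - 2):  # w <= n - 3
                for combo in itertools.combinations(interior, w):
                    chars = list(kmer)
                    for p in combo:
                        chars[p] = "."
                    support.setdefault("".join(chars), set()).add(sid)
    return support


def oracle_enumerate(seqs, n, min_sequences=3, prune=True):
    """Brute-force reference for retained motif enumeration.

    Applies the minimum-support filter and, for degenerate patterns, the
    parent rule: keep only if the count exceeds the best generated parent
    (one fewer wildcard) by at least two.  Returns pattern -> count.
    """
    support = oracle_generate_counts(seqs, n)
    counts = {pat: len(ids) for pat, ids in support.items()}
    out = {}
    for pat, k in counts.items():
        if k < min_sequences:
            continue
        if prune and "." in pat:
            best = 0
            for i, ch in enumerate(pat):
                if ch == ".":
                    for aa in ALPHABET:
                        parent = pat[:i] + aa + pat[i + 1:]
                        if parent in counts:
                            best = max(best, counts[parent])
            if k - best < 2:
                continue
        out[pat] = k
    return out


def oracle_hypergeom_tail(k, l, q, b):
    """Exact rational cumulative hypergeometric upper tail."""
    num = sum(comb(l, i) * comb(b - l, q - i) for i in range(k, min(l, q) + 1))
    return Fraction(num, comb(b, q))
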