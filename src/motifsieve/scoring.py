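"""Overrepresentation scoring of enumerated motifs.

The null model: a query of q sequences is a sample without replacement
from a background of b sequences, of which l contain the motif.  The raw
score is the cumulative hypergeometric tail

    p_raw = P(K >= k) = sum_{i=k}^{min(l,q)} C(l,i) C(b-l, q-i) / C(b,q),

the probability of seeing the motif in at least k query sequences by
chance.  Because longer motifs live in a larger wildcard-placement space
(WC = C(n-2, w) layouts), raw scores are adjusted per motif by a
Sidak-style correction p_adj = 1 - (1 - p_raw)^WC (a Bonferroni switch,
min(1, p_raw * WC), is provided for sensitivity analysis).  Scores depend
only on the counts (k, l, q, b) and on WC — never on motif composition;
compositional biases of the sequence space are absorbed by the background
counts themselves.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

from .enumeration import (
    MIN_LENGTH,
    MAX_LENGTH,
    WILDCARD,
    count_in_background,
    wildcard_combinations,
    _enumerate_engine,
    _decode,
)
from .seqio import MaskAnnotation, SequenceRecord, SequenceSet, apply_mask_annotations

ADJUST_METHODS = ("sidak", "bonferroni")


@dataclasses.dataclass(frozen=True)
class MotifStats:
    """Scored occurrence statistics for one motif.

    k/l: query/background sequence-level occurrence counts; q/b: query and
    background sizes; wc: wildcard-placement multiplicity C(n-2, w).
    """

    pattern: str
    k: int
    l: int
    q: int
    b: int
    wc: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.l, self.q) and self.l <= self.b and self.q <= self.b):
            raise ValueError(
                f"inconsistent counts for {self.pattern!r}: "
                f"k={self.k}, l={self.l}, q={self.q}, b={self.b}"
            )
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adj <= 1.0):
            raise ValueError(f"P-values out of [0, 1] for {self.pattern!r}")

    @property
    def n(self) -> int:
        return len(self.pattern)

    @property
    def w(self) -> int:
        return self.pattern.count(WILDCARD)


def _log_choose(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeometric_tail(k: int, l: int, q: int, b: int) -> float:
    """Cumulative upper tail P(K >= k) of Hypergeometric(b, l, q).

    Accumulated in log space from the k end; exact 1.0 at k = 0 and
    whenever k is at or below the support floor max(0, q + l - b), which
    covers the q = b, k = l boundary.
    """
    for name, value in (("k", k), ("l", l), ("q", q), ("b", b)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if k > q:
        raise ValueError(f"precondition violated: k > q ({k} > {q})")
    if k > l:
        raise ValueError(f"precondition violated: k > l ({k} > {l})")
    if l > b:
        raise ValueError(f"precondition violated: l > b ({l} > {b})")
    if q > b:
        raise ValueError(f"precondition violated: q > b ({q} > {b})")
    if k <= max(0, q + l - b):
        return 1.0
    hi = min(l, q)
    log_denom = _log_choose(b, q)
    logs = [
        _log_choose(l, i) + _log_choose(b - l, q - i) - log_denom
        for i in range(k, hi + 1)
    ]
    m = max(logs)
    total = math.fsum(math.exp(x - m) for x in logs)
    return min(1.0, math.exp(m + math.log(total)))


def adjust_pvalue(p_raw: float, n: int, w: int, method: str = "sidak") -> float:
    """Adjust a raw P-value for the WC = C(n-2, w) wildcard placements.

    Sidak: 1 - (1 - p)^WC (stays within [p, 1]); Bonferroni: min(1, p*WC).
    """
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw must be in [0, 1], got {p_raw}")
    wc = wildcard_combinations(n, w)
    if method == "sidak":
        if p_raw == 0.0:
            return 0.0
        if p_raw == 1.0:
            return 1.0
        return -math.expm1(wc * math.log1p(-p_raw))
    if method == "bonferroni":
        return min(1.0, p_raw * wc)
    raise ValueError(f"unknown adjustment method {method!r}; use one of {ADJUST_METHODS}")


def rank_motifs(stats: Iterable[MotifStats]) -> list[MotifStats]:
    """Deterministic ranking: ascending p_adj, then p_raw, then fewer
    wildcards, then lexicographic pattern."""
    return sorted(stats, key=lambda s: (s.p_adj, s.p_raw, s.w, s.pattern))


def discover(
    query: SequenceSet,
    background: SequenceSet,
    lengths: Iterable[int] = range(3, 11),
    masks: Optional[Sequence[MaskAnnotation]] = None,
    *,
    min_sequences: int = 3,
    adjust: str = "sidak",
    prune: bool = True,
    log=None,
) -> list[MotifStats]:
    """Full discovery pipeline: enumerate, count, score, rank.

    For each requested length: enumerate retained degenerate n-mers of the
    query, count them in the background, score by the hypergeometric tail
    and adjust by wildcard multiplicity; all lengths are merged into one
    ranked list.  The query must have at least three sequences and be a
    subset of the background (same ids, identical residues); query mask
    bits are propagated to the matching background records so a masked
    query window can never out-count its background copy.  ``log``, if
    given, receives one progress line per length with the candidate counts
    at each filtering stage.
    """
    lengths = sorted(set(int(n) for n in lengths))
    for n in lengths:
        if not MIN_LENGTH <= n <= MAX_LENGTH:
            raise ValueError(f"lengths must be within [{MIN_LENGTH}, {MAX_LENGTH}], got {n}")
    if not lengths:
        raise ValueError("no motif lengths requested")
    if len(query) < min_sequences:
        raise ValueError(
            f"query must contain at least {min_sequences} sequences, got {len(query)}"
        )
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {adjust!r}")

    bg_by_id = {rec.id: rec for rec in background}
    offending = [
        rec.id for rec in query
        if rec.id not in bg_by_id or bg_by_id[rec.id].residues != rec.residues
    ]
    if offending:
        raise ValueError(
            "query must be a subset of the background; offending ids: "
            + ", ".join(offending)
        )

    if masks:
        query_ids = set(query.ids())
        bg_ids = set(background.ids())
        query = apply_mask_annotations(
            query, [m for m in masks if m.sequence_id in query_ids]
        )
        background = apply_mask_annotations(
            background, [m for m in masks if m.sequence_id in bg_ids]
        )
        bg_by_id = {rec.id: rec for rec in background}
    # propagate query masks into the shared background copies (on copies,
    # never mutating the caller's records)
    query_masks = {rec.id: rec.mask for rec in query}
    new_bg = []
    for rec in background:
        if rec.id in query_masks and (query_masks[rec.id] & ~rec.mask).any():
            rec = SequenceRecord(
                id=rec.id, residues=rec.residues,
                mask=rec.mask | query_masks[rec.id],
            )
        new_bg.append(rec)
    background = SequenceSet(records=new_bg, role=background.role)

    q_size, b_size = len(query), len(background)
    all_stats: list[MotifStats] = []
    tail_cache: dict[tuple[int, int], float] = {}
    for n in lengths:
        per_layout, counts, retained, summary = _enumerate_engine(
            query.records, n, min_sequences, prune
        )
        index: dict[str, int] = {}
        for lay, (codes, kvec) in counts.items():
            sel = retained[lay]
            if not sel.any():
                continue
            for code, k in zip(codes[sel].tolist(), kvec[sel].tolist()):
                index[_decode(code, lay, n)] = int(k)
        bg_counts = count_in_background(index.keys(), background) if index else {}
        for pat, k in index.items():
            l = bg_counts[pat]
            key = (k, l)
            if key not in tail_cache:
                tail_cache[key] = hypergeometric_tail(k, l, q_size, b_size)
            p_raw = tail_cache[key]
            w = pat.count(WILDCARD)
            all_stats.append(MotifStats(
                pattern=pat, k=k, l=l, q=q_size, b=b_size,
                wc=wildcard_combinations(n, w),
                p_raw=p_raw, p_adj=adjust_pvalue(p_raw, n, w, adjust),
            ))
        if log is not None:
            log(
                f"n={n}: enumerated={summary['patterns']} "
                f"support>={min_sequences}: {summary['support_pass']} "
                f"after pruning: {summary['retained']} scored: {summary['retained']}"
            )
    return rank_motifs(all_stats)
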