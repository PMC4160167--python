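"""Exhaustive enumeration of exact and degenerate n-mers.

A motif is a fixed-length pattern over the 20 amino acids plus the
wildcard ``.``; the first and last positions are always defined and at
least three positions are defined overall, so a length-n motif carries
w = 0 .. n-3 wildcards placed among the n-2 interior positions
(WC = C(n-2, w) layouts).

The enumeration is exact: every unmasked length-n window of the query
generates all of its degenerate variants, variants seen in fewer than
three query sequences are discarded, and a variant is further discarded
when adding its last wildcard gained fewer than two supporting sequences
over the best of its one-wildcard-less parents (such a variant carries no
information beyond the parent).  Occurrences are counted at the sequence
level throughout: a sequence supports a pattern once no matter how many
windows match.

Internally, windows are projected onto each defined-position layout and
packed into base-21 integer codes so that counting reduces to sorts and
unique operations on NumPy arrays; all public values are exact integers.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping

import numpy as np

from .seqio import SequenceRecord, SequenceSet

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "."
MIN_LENGTH = 3
MAX_LENGTH = 12
MIN_DEFINED = 3

_AA_TO_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
_BASE = 21  # 20 residues + one sentinel for non-standard letters
_SENTINEL = 20
_EMPTY = np.empty(0, dtype=np.int64)

#: MotifIndex: pattern string -> set of sequence ids with >=1 unmasked match.
MotifIndex = dict


def _check_length(n: int) -> None:
    if not MIN_LENGTH <= n <= MAX_LENGTH:
        raise ValueError(f"motif length must be in [{MIN_LENGTH}, {MAX_LENGTH}], got {n}")


def validate_pattern(pattern: str) -> None:
    n = len(pattern)
    _check_length(n)
    if pattern[0] == WILDCARD or pattern[-1] == WILDCARD:
        raise ValueError(f"first and last positions must be defined: {pattern!r}")
    d = sum(1 for c in pattern if c != WILDCARD)
    if d < MIN_DEFINED:
        raise ValueError(f"pattern needs >= {MIN_DEFINED} defined positions: {pattern!r}")
    for c in pattern:
        if c != WILDCARD and c not in _AA_TO_CODE:
            raise ValueError(f"invalid character {c!r} in pattern {pattern!r}")


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """A validated motif pattern; ``.`` marks wildcard positions."""

    pattern: str

    def __post_init__(self) -> None:
        validate_pattern(self.pattern)

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        """Parse a pattern, accepting ``x``/``X`` as wildcard aliases."""
        normalized = "".join(
            WILDCARD if c in ".xX" else c.upper() for c in text.strip()
        )
        return cls(normalized)

    @property
    def n(self) -> int:
        return len(self.pattern)

    @property
    def d(self) -> int:
        return sum(1 for c in self.pattern if c != WILDCARD)

    @property
    def w(self) -> int:
        return self.n - self.d

    def __str__(self) -> str:
        return self.pattern

    def __len__(self) -> int:
        return len(self.pattern)


def max_index_size(seqs: SequenceSet, n: int) -> int:
    """Upper bound S on the exact n-mer index: sum_i max(0, L_i - n + 1)."""
    _check_length(n)
    return sum(max(0, len(rec) - n + 1) for rec in seqs)


def wildcard_combinations(n: int, w: int) -> int:
    """Number of wildcard placements WC = C(n-2, w) for a length-n motif."""
    _check_length(n)
    if w < 0 or w > n - MIN_DEFINED:
        raise ValueError(f"wildcard count must be in [0, {n - MIN_DEFINED}] for n={n}, got {w}")
    return math.comb(n - 2, w)


def motif_space_size(n: int, d: int) -> int:
    """Size of the motif space at length n with d defined positions.

    20^d residue choices times C(n-2, d-2) placements of the d-2 defined
    interior positions (first and last are always defined).
    """
    _check_length(n)
    if d < MIN_DEFINED:
        raise ValueError(f"need >= {MIN_DEFINED} defined positions, got {d}")
    if d > n:
        raise ValueError(f"defined positions d={d} exceed length n={n}")
    return 20 ** d * math.comb(n - 2, d - 2)


def degenerate_variants(kmer: str) -> list[str]:
    """All degenerate forms of an exact k-mer, including itself.

    Wildcards replace interior positions in every combination and number
    up to n-3, keeping the first and last positions and at least three
    defined positions.  List size is sum_{w=0}^{n-3} C(n-2, w).
    """
    n = len(kmer)
    _check_length(n)
    if WILDCARD in kmer:
        raise ValueError(f"expected an exact k-mer without wildcards: {kmer!r}")
    interior = range(1, n - 1)
    out = []
    for w in range(0, n - 2):  # w <= n-3
        for combo in itertools.combinations(interior, w):
            chars = list(kmer)
            for p in combo:
                chars[p] = WILDCARD
            out.append("".join(chars))
    return out


def match_pattern(pattern, record: SequenceRecord, return_positions: bool = False):
    """Does the record contain an unmasked window matching the pattern?

    Defined positions must equal the residue; wildcards match any residue
    but never a masked one (a masked region contributes no support).
    """
    pat = str(pattern)
    n = len(pat)
    res = record.residues
    mask = record.mask
    positions = []
    for i in range(len(res) - n + 1):
        if mask[i:i + n].any():
            continue
        if all(pc == WILDCARD or pc == res[i + j] for j, pc in enumerate(pat)):
            if not return_positions:
                return True
            positions.append(i)
    if return_positions:
        return positions
    return False


def enumerate_exact_kmers(query: SequenceSet, n: int) -> MotifIndex:
    """Index every fully unmasked length-n window of the query.

    Returns pattern -> set of sequence ids; windows overlapping a masked
    position are skipped.
    """
    _check_length(n)
    index: dict[str, set[str]] = {}
    for rec in query:
        res = rec.residues
        mask = rec.mask
        valid = _valid_starts(mask, n)
        for i in np.flatnonzero(valid):
            index.setdefault(res[i:i + n], set()).add(rec.id)
    return index


# ---------------------------------------------------------------------------
# layout/code machinery


def _encode_record(rec: SequenceRecord) -> np.ndarray:
    return np.fromiter(
        (_AA_TO_CODE.get(c, _SENTINEL) for c in rec.residues),
        dtype=np.int64, count=len(rec.residues),
    )


def _valid_starts(mask: np.ndarray, n: int) -> np.ndarray:
    """Boolean array over window starts: True iff no position is masked."""
    length = mask.shape[0]
    w = length - n + 1
    if w <= 0:
        return np.zeros(0, dtype=bool)
    cs = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    return (cs[n:] - cs[:-n]) == 0


def _layouts(n: int) -> list[tuple[int, ...]]:
    """All defined-position layouts for length n: first/last + >=1 interior."""
    interior = tuple(range(1, n - 1))
    out = []
    for c in range(1, n - 1):  # c = d - 2
        for combo in itertools.combinations(interior, c):
            out.append((0,) + combo + (n - 1,))
    return out


def _pack(cols: list[np.ndarray], layout: tuple[int, ...]) -> np.ndarray:
    code = cols[layout[0]].copy()
    for off in layout[1:]:
        code *= _BASE
        code += cols[off]
    return code


def _decode(code: int, layout: tuple[int, ...], n: int) -> str:
    chars = [WILDCARD] * n
    for off in reversed(layout):
        chars[off] = ALPHABET[code % _BASE]
        code //= _BASE
    return "".join(chars)


def _pattern_layout_code(pattern: str) -> tuple[tuple[int, ...], int]:
    layout = tuple(i for i, c in enumerate(pattern) if c != WILDCARD)
    code = 0
    for i in layout:
        code = code * _BASE + _AA_TO_CODE[pattern[i]]
    return layout, code


def _drop_digit(codes: np.ndarray, j: int, ndigits: int) -> np.ndarray:
    """Remove the j-th base-21 digit (0 = most significant) from packed codes."""
    place = _BASE ** (ndigits - 1 - j)
    hi = codes // (place * _BASE)
    lo = codes % place
    return hi * place + lo


def _grouped_max(keys: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if keys.size == 0:
        return keys, vals
    order = np.argsort(keys)
    k2, v2 = keys[order], vals[order]
    starts = np.flatnonzero(np.concatenate(([True], k2[1:] != k2[:-1])))
    return k2[starts], np.maximum.reduceat(v2, starts)


def _lookup(sorted_keys: np.ndarray, vals: np.ndarray, queries: np.ndarray,
            default: int = 0) -> np.ndarray:
    if sorted_keys.size == 0:
        return np.full(queries.shape, default, dtype=vals.dtype if vals.size else np.int64)
    pos = np.searchsorted(sorted_keys, queries)
    pos_c = np.minimum(pos, sorted_keys.size - 1)
    hit = (pos < sorted_keys.size) & (sorted_keys[pos_c] == queries)
    return np.where(hit, vals[pos_c], default)


def _layout_tables(records, n: int) -> dict[tuple[int, ...], list[np.ndarray]]:
    """Per layout, per record: sorted unique packed codes of valid windows."""
    layouts = _layouts(n)
    per_layout: dict[tuple[int, ...], list[np.ndarray]] = {lay: [] for lay in layouts}
    for rec in records:
        w = len(rec) - n + 1
        valid = _valid_starts(rec.mask, n) if w > 0 else None
        if w <= 0 or not valid.any():
            for lay in layouts:
                per_layout[lay].append(_EMPTY)
            continue
        arr = _encode_record(rec)
        cols = [arr[off:off + w][valid] for off in range(n)]
        for lay in layouts:
            per_layout[lay].append(np.unique(_pack(cols, lay)))
    return per_layout


def _enumerate_engine(records, n: int, min_sequences: int, prune: bool):
    """Shared core: returns (per_layout tables, counts, retained masks, summary)."""
    per_layout = _layout_tables(records, n)
    counts: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}
    for lay, chunks in per_layout.items():
        allc = np.concatenate(chunks) if chunks else _EMPTY
        codes, k = np.unique(allc, return_counts=True)
        counts[lay] = (codes, k.astype(np.int64))

    summary = {"patterns": 0, "support_pass": 0, "retained": 0}
    retained: dict[tuple[int, ...], np.ndarray] = {}
    for lay, (codes, k) in counts.items():
        summary["patterns"] += codes.size
        keep = k >= min_sequences
        summary["support_pass"] += int(keep.sum())
        if prune and len(lay) < n and keep.any():
            max_parent = np.zeros(codes.size, dtype=np.int64)
            for p in range(1, n - 1):
                if p in lay:
                    continue
                parent_lay = tuple(sorted(lay + (p,)))
                pcodes, pk = counts[parent_lay]
                if pcodes.size == 0:
                    continue
                j = parent_lay.index(p)
                proj = _drop_digit(pcodes, j, len(parent_lay))
                gkeys, gmax = _grouped_max(proj, pk)
                max_parent = np.maximum(max_parent, _lookup(gkeys, gmax, codes))
            keep &= (k - max_parent) >= 2
        retained[lay] = keep
        summary["retained"] += int(keep.sum())
    return per_layout, counts, retained, summary


def enumerate_motifs(query: SequenceSet, n: int, min_sequences: int = 3,
                     prune: bool = True) -> MotifIndex:
    """Enumerate all retained degenerate n-mers of the query.

    A pattern is retained when (a) it occurs in at least ``min_sequences``
    query sequences and (b), for patterns with wildcards, its sequence
    count exceeds the best of its single-step parents (one fewer wildcard,
    generated from the same windows) by at least two — replacing a residue
    by a wildcard must add more than one occurrence to be informative.

    Returns pattern -> set of supporting sequence ids.
    """
    _check_length(n)
    if len(query) < min_sequences:
        raise ValueError(
            f"query must contain at least {min_sequences} sequences, got {len(query)}"
        )
    per_layout, counts, retained, _ = _enumerate_engine(
        query.records, n, min_sequences, prune
    )
    index: dict[str, set[str]] = {}
    for lay, (codes, _k) in counts.items():
        sel = retained[lay]
        if not sel.any():
            continue
        rc = codes[sel]
        patterns = {int(c): _decode(int(c), lay, n) for c in rc}
        for pat in patterns.values():
            index[pat] = set()
        for rec, uniq in zip(query.records, per_layout[lay]):
            if uniq.size == 0:
                continue
            hits = uniq[np.isin(uniq, rc, assume_unique=True)]
            for c in hits.tolist():
                index[patterns[c]].add(rec.id)
    return index


def count_in_background(patterns: Iterable[str], background: SequenceSet
                        ) -> Mapping[str, int]:
    """Sequence-level occurrence counts l of each pattern in the background.

    Each background sequence counts once per pattern regardless of how
    many windows match; masked positions never contribute.
    """
    if len(background) == 0:
        raise ValueError("background is empty")
    wanted: dict[tuple[int, tuple[int, ...]], dict[int, str]] = {}
    for pat in patterns:
        pat = str(pat)
        validate_pattern(pat)
        layout, code = _pattern_layout_code(pat)
        wanted.setdefault((len(pat), layout), {})[code] = pat

    targets = {
        key: (np.array(sorted(codemap), dtype=np.int64), np.zeros(len(codemap), np.int64))
        for key, codemap in wanted.items()
    }
    lengths = sorted({n for n, _ in wanted})
    by_n = {n: [lay for (m, lay) in wanted if m == n] for n in lengths}

    for rec in background:
        arr = None
        for n in lengths:
            w = len(rec) - n + 1
            if w <= 0:
                continue
            valid = _valid_starts(rec.mask, n)
            if not valid.any():
                continue
            if arr is None:
                arr = _encode_record(rec)
            cols = [arr[off:off + w][valid] for off in range(n)]
            for lay in by_n[n]:
                tgt, counter = targets[(n, lay)]
                uniq = np.unique(_pack(cols, lay))
                pos = np.searchsorted(tgt, uniq)
                pos_c = np.minimum(pos, tgt.size - 1)
                hit = (pos < tgt.size) & (tgt[pos_c] == uniq)
                counter[pos_c[hit]] += 1

    out: dict[str, int] = {}
    for key, codemap in wanted.items():
        tgt, counter = targets[key]
        code_to_count = dict(zip(tgt.tolist(), counter.tolist()))
        for code, pat in codemap.items():
            out[pat] = code_to_count[code]
    return out
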