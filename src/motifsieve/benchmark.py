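"""Spike-in benchmark: synthetic proteomes, masks, motifs, spiked sets.

The benchmark measures how reliably the discovery pipeline recovers a
known motif written into a set of sequences.  Its dimensions are the
motif length n (3-10), the number of defined positions d (3-n) and the
number of spiked occurrences N.  For each (n, d) a binary mask fixes
which positions are defined; each mask derives a batch of unique motifs
by shuffling the interior defined/wildcard layout and drawing amino acids
from proteome-like frequencies; each motif is spiked once into N of the
set's sequences (at most one occurrence per sequence, wildcard positions
re-drawn at every insertion so only the defined positions are shared).
A set counts as correctly solved when the top-ranked discovered pattern
equals the spiked pattern exactly; accuracy is correct / replicates per
(n, d, N) cell.

The full-size grid — lengths 3-10, d = 3..n (36 masks), 30 replicates,
N in {3,4,5,6,7,8,10,12,15,20,30} — comprises 1080 motifs and 11,880
spiked sets.  Everything is a pure function of (configuration, seed);
per-set seeds are derived from the master seed by stable hashing so any
set can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enumeration import ALPHABET, WILDCARD, MotifPattern
from .seqio import SequenceRecord, SequenceSet, write_fasta
from .scoring import MotifStats, discover

#: Amino-acid frequencies of a yeast-like proteome (normalized at load).
YEAST_AA_FREQS: dict[str, float] = {
    "A": 0.0551, "C": 0.0132, "D": 0.0585, "E": 0.0656, "F": 0.0441,
    "G": 0.0499, "H": 0.0217, "I": 0.0657, "K": 0.0730, "L": 0.0957,
    "M": 0.0209, "N": 0.0613, "P": 0.0435, "Q": 0.0393, "R": 0.0445,
    "S": 0.0902, "T": 0.0592, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}

_DEFAULT_FREQS = np.array([YEAST_AA_FREQS[a] for a in ALPHABET], dtype=float)
_DEFAULT_FREQS /= _DEFAULT_FREQS.sum()

FULL_OCCURRENCES = (3, 4, 5, 6, 7, 8, 10, 12, 15, 20, 30)


def _freq_vector(aa_freqs) -> np.ndarray:
    if aa_freqs is None:
        return _DEFAULT_FREQS
    if isinstance(aa_freqs, Mapping):
        vec = np.array([aa_freqs[a] for a in ALPHABET], dtype=float)
    else:
        vec = np.asarray(aa_freqs, dtype=float)
    if vec.shape != (20,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(
            "invalid frequency vector: need 20 non-negative values summing to 1"
        )
    return vec


def _child_seed(master: int, label: str) -> int:
    """Stable sub-seed derived from a master seed and a label (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def generate_synthetic_proteome(
    count: int,
    length_range: tuple[int, int] = (100, 500),
    aa_freqs=None,
    seed: int = 0,
) -> SequenceSet:
    """Draw a synthetic background proteome.

    Lengths are uniform over ``length_range`` (inclusive) and residues are
    i.i.d. draws from ``aa_freqs``; deterministic for a fixed seed.
    """
    lo, hi = length_range
    if count < 1:
        raise ValueError("count must be >= 1")
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    freqs = _freq_vector(aa_freqs)
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=count)
    letters = np.array(list(ALPHABET))
    draws = rng.choice(20, size=int(lengths.sum()), p=freqs)
    records = []
    offset = 0
    for i, length in enumerate(lengths):
        chunk = draws[offset:offset + int(length)]
        offset += int(length)
        records.append(SequenceRecord(
            id=f"syn{i + 1:05d}",
            residues="".join(letters[chunk]),
            mask=np.zeros(int(length), dtype=bool),
        ))
    return SequenceSet(records=records, role="background")


@dataclasses.dataclass(frozen=True)
class BenchmarkMask:
    """Binary defined/wildcard layout; 1 = defined.  Ends always defined."""

    n: int
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != self.n:
            raise ValueError("bits length must equal n")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")
        if self.bits[0] != 1 or self.bits[-1] != 1:
            raise ValueError("first and last positions must be defined")
        if sum(self.bits) < 3:
            raise ValueError("mask needs at least 3 defined positions")

    @property
    def d(self) -> int:
        return sum(self.bits)


def canonical_mask(n: int, d: int) -> BenchmarkMask:
    """Canonical layout: ends defined, remaining d-2 ones leftmost."""
    if not 3 <= d <= n:
        raise ValueError(f"need 3 <= d <= n, got d={d}, n={n}")
    bits = [0] * n
    bits[0] = bits[-1] = 1
    for i in range(1, d - 1):
        bits[i] = 1
    return BenchmarkMask(n=n, bits=tuple(bits))


def generate_masks(lengths: Iterable[int] = range(3, 11)) -> list[BenchmarkMask]:
    """One mask per (n, d) with d = 3..n: n-2 masks per length, 36 for 3-10."""
    masks = []
    for n in sorted(set(int(x) for x in lengths)):
        if n < 3:
            raise ValueError(f"mask lengths must be >= 3, got {n}")
        for d in range(3, n + 1):
            masks.append(canonical_mask(n, d))
    return masks


def derive_motifs(
    mask: BenchmarkMask,
    replicates: int = 30,
    aa_freqs=None,
    seed: int = 0,
) -> list[MotifPattern]:
    """Derive ``replicates`` mutually distinct motifs from one mask.

    Each motif keeps the mask's (n, d): the interior defined/wildcard
    layout is shuffled independently per replicate and defined positions
    are filled with amino acids drawn from ``aa_freqs``.  Collisions are
    resampled; deterministic per seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n, d = mask.n, mask.d
    space = math.comb(n - 2, d - 2) * 20 ** d
    if space < replicates:
        raise ValueError(
            f"pattern space for n={n}, d={d} holds only {space} motifs, "
            f"cannot derive {replicates} distinct ones"
        )
    freqs = _freq_vector(aa_freqs)
    rng = np.random.default_rng(seed)
    interior = list(range(1, n - 1))
    out: list[MotifPattern] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < replicates:
        attempts += 1
        if attempts > 1000 * replicates:
            raise RuntimeError("failed to derive distinct motifs (space too tight)")
        chosen = sorted(rng.permutation(interior)[: d - 2].tolist()) if interior else []
        defined = [0] + [int(p) for p in chosen] + [n - 1]
        residues = rng.choice(20, size=d, p=freqs)
        chars = [WILDCARD] * n
        for pos, aa in zip(defined, residues):
            chars[pos] = ALPHABET[int(aa)]
        pattern = "".join(chars)
        if pattern not in seen:
            seen.add(pattern)
            out.append(MotifPattern(pattern))
    return out


def spike_motif(
    seqs: SequenceSet,
    motif,
    N: int,
    seed: int = 0,
    aa_freqs=None,
) -> SequenceSet:
    """Overwrite one window in each of N distinct sequences with the motif.

    The window position is uniform within each chosen sequence; wildcard
    positions are filled with fresh draws from ``aa_freqs`` at every
    insertion, so only the defined positions are shared across the N
    instances.  Sequence count, ids, order and lengths are unchanged.
    """
    pattern = str(motif)
    n = len(pattern)
    if N < 0:
        raise ValueError("N must be >= 0")
    if N > len(seqs):
        raise ValueError(f"N={N} exceeds set size {len(seqs)}")
    freqs = _freq_vector(aa_freqs)
    rng = np.random.default_rng(seed)
    eligible = [i for i, rec in enumerate(seqs.records) if len(rec) > n]
    if len(eligible) < N:
        raise ValueError(
            f"only {len(eligible)} sequences are longer than the motif (need {N})"
        )
    chosen = set(
        int(eligible[j]) for j in rng.choice(len(eligible), size=N, replace=False)
    ) if N else set()
    records = []
    for i, rec in enumerate(seqs.records):
        if i not in chosen:
            records.append(rec)
            continue
        pos = int(rng.integers(0, len(rec) - n + 1))
        chars = list(pattern)
        for j, c in enumerate(chars):
            if c == WILDCARD:
                chars[j] = ALPHABET[int(rng.choice(20, p=freqs))]
        residues = rec.residues[:pos] + "".join(chars) + rec.residues[pos + n:]
        records.append(SequenceRecord(id=rec.id, residues=residues, mask=rec.mask.copy()))
    return SequenceSet(records=records, role=seqs.role)


@dataclasses.dataclass(frozen=True)
class SpikeManifest:
    """Ground-truth record for one spiked benchmark set."""

    set_id: str
    pattern: str
    n: int
    d: int
    N: int
    replicate: int
    seed: int
    query_path: Optional[str] = None
    background_path: Optional[str] = None


@dataclasses.dataclass
class BenchmarkConfig:
    lengths: tuple[int, ...] = tuple(range(3, 11))
    occurrences: tuple[int, ...] = FULL_OCCURRENCES
    replicates: int = 30
    set_size: int = 100


def realize_spiked_set(
    background: SequenceSet,
    motif,
    N: int,
    set_size: int,
    seed: int,
    aa_freqs=None,
) -> tuple[SequenceSet, SequenceSet]:
    """Materialize one benchmark set from its seed.

    Samples ``set_size`` background sequences without replacement, spikes
    the motif into N of them, and returns (query, per-set background)
    where the per-set background is the full background with the sampled
    sequences replaced by their spiked versions — the query is a strict
    subset of it.
    """
    if len(background) < set_size:
        raise ValueError(
            f"background of {len(background)} sequences cannot supply "
            f"sets of {set_size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(background), size=set_size, replace=False)
    spike_seed = int(rng.integers(0, 2 ** 31))
    subset = [background.records[int(i)] for i in idx]
    query = spike_motif(
        SequenceSet(records=subset, role="query"), motif, N, spike_seed, aa_freqs
    )
    spiked_by_id = {rec.id: rec for rec in query}
    bg_records = [spiked_by_id.get(rec.id, rec) for rec in background]
    return query, SequenceSet(records=bg_records, role="background")


def build_benchmark(
    config: BenchmarkConfig,
    background: SequenceSet,
    seed: int,
    out_dir: Optional[str | Path] = None,
    aa_freqs=None,
) -> list[SpikeManifest]:
    """Build the full spike-in benchmark manifest (and optionally its files).

    Manifest size = #masks x replicates x #occurrence values.  With
    ``out_dir`` set, each set's query and per-set background FASTA are
    written and their paths recorded; without it only the (fully
    reproducible) manifest is produced and any set can be regenerated
    later with :func:`realize_spiked_set`.
    """
    if len(background) < config.set_size:
        raise ValueError(
            f"background of {len(background)} sequences cannot supply "
            f"sets of {config.set_size}"
        )
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    manifest: list[SpikeManifest] = []
    for mask in generate_masks(config.lengths):
        motifs = derive_motifs(
            mask, config.replicates, aa_freqs,
            _child_seed(seed, f"motifs:n{mask.n}:d{mask.d}"),
        )
        for r, motif in enumerate(motifs, start=1):
            for N in config.occurrences:
                set_id = f"n{mask.n}_d{mask.d}_r{r:02d}_N{N:02d}"
                sseed = _child_seed(seed, set_id)
                qpath = bpath = None
                if out_path is not None:
                    query, per_bg = realize_spiked_set(
                        background, motif, N, config.set_size, sseed, aa_freqs
                    )
                    qpath = str(out_path / f"{set_id}_query.fasta")
                    bpath = str(out_path / f"{set_id}_background.fasta")
                    write_fasta(query, qpath)
                    write_fasta(per_bg, bpath)
                manifest.append(SpikeManifest(
                    set_id=set_id, pattern=str(motif), n=mask.n, d=mask.d,
                    N=N, replicate=r, seed=sseed,
                    query_path=qpath, background_path=bpath,
                ))
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.tsv")
    return manifest


_MANIFEST_COLUMNS = (
    "set_id", "pattern", "n", "d", "N", "replicate", "seed",
    "query_path", "background_path",
)


def write_manifest(manifest: Sequence[SpikeManifest], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for m in manifest:
            fh.write("\t".join(str(getattr(m, c) if getattr(m, c) is not None else "-")
                               for c in _MANIFEST_COLUMNS) + "\n")


def read_manifest(path: str | Path) -> list[SpikeManifest]:
    out = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != _MANIFEST_COLUMNS:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(SpikeManifest(
                set_id=f[0], pattern=f[1], n=int(f[2]), d=int(f[3]), N=int(f[4]),
                replicate=int(f[5]), seed=int(f[6]),
                query_path=None if f[7] == "-" else f[7],
                background_path=None if f[8] == "-" else f[8],
            ))
    return out


@dataclasses.dataclass
class AccuracyReport:
    """Per-(n, d, N) top-motif identification accuracy."""

    cells: dict[tuple[int, int, int], tuple[int, int]]

    def accuracy(self, n: int, d: int, N: int) -> float:
        correct, total = self.cells[(n, d, N)]
        return correct / total

    def overall(self) -> float:
        correct = sum(c for c, _ in self.cells.values())
        total = sum(t for _, t in self.cells.values())
        return correct / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n": n, "d": d, "N": N, "correct": c, "replicates": t,
             "accuracy": c / t}
            for (n, d, N), (c, t) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["n", "d", "N", "correct", "replicates", "accuracy"])


def evaluate_topmotif_accuracy(
    results: Mapping[str, Sequence[MotifStats]],
    manifest: Sequence[SpikeManifest],
) -> AccuracyReport:
    """Score each set: correct iff its rank-1 pattern equals the spiked one."""
    cells: dict[tuple[int, int, int], list[int]] = {}
    for entry in manifest:
        if entry.set_id not in results:
            raise ValueError(f"no result list for benchmark set {entry.set_id!r}")
        ranked = results[entry.set_id]
        correct = bool(ranked) and ranked[0].pattern == entry.pattern
        cell = cells.setdefault((entry.n, entry.d, entry.N), [0, 0])
        cell[0] += int(correct)
        cell[1] += 1
    return AccuracyReport(cells={k: (v[0], v[1]) for k, v in cells.items()})


def spike_recovery_accuracy(
    background: SequenceSet,
    *,
    n: int,
    d: int,
    N: int,
    replicates: int,
    lengths: Iterable[int],
    seed: int,
    set_size: int = 100,
    aa_freqs=None,
    adjust: str = "sidak",
) -> float:
    """End-to-end recovery rate for one (n, d, N) benchmark cell.

    Derives ``replicates`` distinct motifs from the canonical (n, d) mask,
    spikes each into its own set of ``set_size`` sequences sampled from
    ``background``, runs discovery over ``lengths`` and returns the
    fraction of sets whose top-ranked pattern equals the spiked motif.
    """
    mask = canonical_mask(n, d)
    motifs = derive_motifs(mask, replicates, aa_freqs, _child_seed(seed, "motifs"))
    lengths = tuple(lengths)
    correct = 0
    for r, motif in enumerate(motifs):
        query, per_bg = realize_spiked_set(
            background, motif, N, set_size, _child_seed(seed, f"set:{r}"), aa_freqs
        )
        ranked = discover(query, per_bg, lengths, adjust=adjust)
        if ranked and ranked[0].pattern == str(motif):
            correct += 1
    return correct / replicates
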