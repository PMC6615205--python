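"""Simulation of concatenated-fragment ("SMURF-seq style") long reads.

The simulator mirrors how such libraries are made: a restriction digest
produces a pool of short fragments; re-ligation concatenates random fragments
in random orientation into long molecules; nanopore sequencing then corrupts
the molecule with substitutions and indels.  Every simulated read carries a
full per-fragment truth record (:class:`FragmentTruth`): the source reference
interval and strand, and the fragment's interval within the finished read in
*post-error* coordinates, so mapper evaluation works directly in final read
space.

Fragment sampling is weighted by the local copy number at the fragment
midpoint, which is what turns a planted copy-number truth into a read-count
signal downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import CnvTruth, ParameterError, ReferenceGenome

__all__ = [
    "FragmentTruth",
    "SmurfRead",
    "ErrorModel",
    "OriginRead",
    "sample_fragments",
    "concatenate",
    "apply_errors",
    "splice_from_reads",
    "simulate_reads",
]

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class FragmentTruth:
    """Ground truth for one fragment embedded in a read."""

    source_chrom: str
    source_start: int
    source_end: int
    strand: str  # '+' or '-'
    read_start: int
    read_end: int


@dataclass
class SmurfRead:
    """A long read composed of an ordered list of fragments."""

    read_id: str
    sequence: str
    fragments: list[FragmentTruth]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ParameterError("a read needs at least one fragment")
        if self.fragments[-1].read_end != len(self.sequence):
            raise ParameterError("fragment truth does not tile the read")


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitution / insertion / deletion process.

    Defaults emulate R9-era nanopore identity (~88%): sub 0.05, ins 0.03,
    del 0.04.  Each rate must be in [0, 0.5).
    """

    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 0.5:
                raise ParameterError("error rates must be in [0, 0.5)")


def sample_fragments(
    digest: dict[str, np.ndarray],
    truth: CnvTruth,
    n: int,
    seed: int = 0,
    min_length: int = 1,
) -> list[tuple[str, int, int, str]]:
    """Draw ``n`` fragments (with replacement) weighted by local copy number.

    Each digest fragment is drawn with probability proportional to the copy
    number at its midpoint; strand is Bernoulli(0.5).  ``min_length``
    restricts the pool to fragments at least that long (a size-selection
    knob; 1 keeps everything).  Returns ``(chrom, start, end, strand)``
    tuples; deterministic given ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    chroms: list[str] = []
    ivs: list[np.ndarray] = []
    for chrom, arr in digest.items():
        keep = arr[(arr[:, 1] - arr[:, 0]) >= min_length]
        if len(keep):
            chroms.extend([chrom] * len(keep))
            ivs.append(keep)
    if not ivs:
        raise ParameterError("digest is empty (after min_length filter)")
    intervals = np.vstack(ivs)
    chrom_arr = np.array(chroms)
    mids = (intervals[:, 0] + intervals[:, 1]) // 2
    weights = truth.copy_numbers_at(chrom_arr, mids).astype(float)
    total = weights.sum()
    if total == 0:
        raise ParameterError("all copy numbers are zero: no sampling mass")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(intervals), size=n, replace=True, p=weights / total)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return [
        (chrom_arr[i], int(intervals[i, 0]), int(intervals[i, 1]), s)
        for i, s in zip(idx, strands)
    ]


def concatenate(
    fragments: list[tuple[str, int, int, str]],
    genome: ReferenceGenome,
    target_read_len: int,
    read_id_prefix: str = "read",
) -> list[SmurfRead]:
    """Pack sampled fragments, in order, into error-free reads.

    A read is closed when appending the next fragment would exceed
    ``target_read_len``; the fragment that did not fit opens the next read
    (ligation never splits a molecule, so read lengths spread by about one
    fragment).  Reverse-strand fragments are reverse-complemented before
    insertion.  Total fragments across reads equals the number sampled.
    """
    max_frag = max(e - s for _, s, e, _ in fragments)
    if target_read_len < max_frag:
        raise ParameterError(
            f"target_read_len {target_read_len} < longest fragment {max_frag}"
        )
    reads: list[SmurfRead] = []
    parts: list[str] = []
    truths: list[FragmentTruth] = []
    pos = 0

    def close() -> None:
        nonlocal parts, truths, pos
        if truths:
            reads.append(
                SmurfRead(f"{read_id_prefix}{len(reads)}", "".join(parts), truths)
            )
        parts, truths, pos = [], [], 0

    for chrom, start, end, strand in fragments:
        frag_len = end - start
        if pos + frag_len > target_read_len:
            close()
        seq = genome[chrom][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
        truths.append(FragmentTruth(chrom, start, end, strand, pos, pos + frag_len))
        pos += frag_len
    close()
    return reads


def apply_errors(read: SmurfRead, model: ErrorModel) -> SmurfRead:
    """Corrupt a read with the error model, remapping truth coordinates.

    Per original base: deleted with ``del_rate``; otherwise emitted, with a
    substitution (to a uniformly random *different* base) at ``sub_rate``;
    then a uniformly random base is inserted after it with ``ins_rate``.
    Fragment read intervals are updated to post-error coordinates (a fully
    deleted fragment keeps a zero-length interval).  Deterministic given the
    model seed and the read id.
    """
    if model.sub_rate == model.ins_rate == model.del_rate == 0.0:
        return read
    # per-read child seed keeps reads independent yet reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed, _stable_hash(read.read_id)])
    )
    arr = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    deleted = rng.random(n) < model.del_rate
    inserted = (rng.random(n) < model.ins_rate) & ~deleted
    substituted = (rng.random(n) < model.sub_rate) & ~deleted

    out = arr.copy()
    if substituted.any():
        # shift by 1..3 in base space => always a different base
        codes = _to_codes(out[substituted])
        shift = rng.integers(1, 4, size=substituted.sum())
        out[substituted] = _FROM_CODES[(codes + shift) % 4]

    contrib = (~deleted).astype(np.int64) + inserted
    new_pos = np.concatenate(([0], np.cumsum(contrib)))  # orig coord -> new coord
    new_len = int(new_pos[-1])
    new_arr = np.empty(new_len, dtype=np.uint8)
    keep_targets = new_pos[:-1][~deleted]
    new_arr[keep_targets] = out[~deleted]
    ins_targets = new_pos[1:][inserted] - 1
    new_arr[ins_targets] = _FROM_CODES[rng.integers(0, 4, size=int(inserted.sum()))]

    new_fragments = [
        replace(
            f,
            read_start=int(new_pos[f.read_start]),
            read_end=int(new_pos[f.read_end]),
        )
        for f in read.fragments
    ]
    return SmurfRead(read.read_id, new_arr.tobytes().decode("ascii"), new_fragments)


_FROM_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TO_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _TO_CODES[_b] = _i


def _to_codes(arr: np.ndarray) -> np.ndarray:
    return _TO_CODES[arr]


def _stable_hash(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


@dataclass(frozen=True)
class OriginRead:
    """A source read with a known reference origin, for splice simulation."""

    sequence: str
    chrom: str
    ref_start: int
    strand: str = "+"


def splice_from_reads(
    source_reads: list[OriginRead],
    fragment_lengths: np.ndarray | list[int],
    target_read_len: int,
    n_fragments: int,
    seed: int = 0,
    read_id_prefix: str = "spliced",
) -> list[SmurfRead]:
    """Build concatenated reads by cutting random substrings out of source
    reads with known origins.

    ``fragment_lengths`` is an empirical length pool sampled with replacement
    (the length distribution is deliberately a free parameter).  Each cut
    substring inherits truth from its source read's origin interval, assuming
    the source read is coordinate-faithful to its origin (true for error-free
    simulated sources).  Fragments are packed into reads exactly like
    :func:`concatenate`.
    """
    lengths = np.asarray(fragment_lengths, dtype=np.int64)
    if lengths.size == 0 or (lengths < 1).any():
        raise ParameterError("fragment_lengths must be positive")
    max_src = max(len(r.sequence) for r in source_reads)
    if lengths.min() > max_src:
        raise ParameterError("every fragment length exceeds every source read")
    rng = np.random.default_rng(seed)

    reads: list[SmurfRead] = []
    parts: list[str] = []
    truths: list[FragmentTruth] = []
    pos = 0

    def close() -> None:
        nonlocal parts, truths, pos
        if truths:
            reads.append(
                SmurfRead(f"{read_id_prefix}{len(reads)}", "".join(parts), truths)
            )
        parts, truths, pos = [], [], 0

    drawn = 0
    while drawn < n_fragments:
        flen = int(lengths[rng.integers(0, lengths.size)])
        fits = [r for r in source_reads if len(r.sequence) >= flen]
        if not fits:
            continue
        src = fits[rng.integers(0, len(fits))]
        off = int(rng.integers(0, len(src.sequence) - flen + 1))
        sub = src.sequence[off : off + flen]
        if src.strand == "+":
            ref_start = src.ref_start + off
        else:
            ref_start = src.ref_start + (len(src.sequence) - off - flen)
        if pos + flen > target_read_len:
            close()
        parts.append(sub)
        truths.append(
            FragmentTruth(src.chrom, ref_start, ref_start + flen, src.strand, pos, pos + flen)
        )
        pos += flen
        drawn += 1
    close()
    return reads


def simulate_reads(
    genome: ReferenceGenome,
    truth: CnvTruth,
    digest: dict[str, np.ndarray],
    n_fragments: int,
    target_read_len: int = 7000,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    min_fragment_length: int = 1,
) -> list[SmurfRead]:
    """End-to-end convenience: sample, concatenate, and optionally corrupt."""
    frags = sample_fragments(
        digest, truth, n_fragments, seed=seed, min_length=min_fragment_length
    )
    reads = concatenate(frags, genome, target_read_len)
    if error_model is not None and (
        error_model.sub_rate or error_model.ins_rate or error_model.del_rate
    ):
        reads = [apply_errors(r, error_model) for r in reads]
    return reads
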