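"""Synthetic reference genomes, planted copy-number truth, and in-silico
restriction digestion.

A :class:`ReferenceGenome` is a small stand-in for a real assembly: a few
chromosomes of i.i.d. bases with a controllable GC composition (optionally a
linear GC gradient along each chromosome, useful for exercising GC-bias
correction).  Copy-number truth is a partition of every chromosome into
integer-copy-number segments (:class:`CnvTruth`); diploid neutral is copy
number 2.

Restriction digestion scans the forward strand for exact occurrences of the
enzyme's recognition site and cuts at ``site_start + cut_offset``.  Both
built-in enzymes (SaqAI ``T^TAA`` and Hin1II ``CATG^``) have palindromic
sites, so a forward-strand scan finds every cut; enzymes with non-palindromic
sites would need a double-strand scan, which is out of scope here.  Runs of
``N`` never match a site, so assembly gaps are never cut inside.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "ReferenceGenome",
    "CnvTruthSegment",
    "CnvTruth",
    "RestrictionEnzyme",
    "SAQAI",
    "HIN1II",
    "ENZYMES",
    "generate_genome",
    "plant_cnv",
    "digest",
    "fragment_length_stats",
]


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


@dataclass
class ReferenceGenome:
    """Multi-chromosome DNA reference held in memory.

    Parameters
    ----------
    chrom_names
        Ordered, unique chromosome identifiers.
    sequences
        Uppercase DNA strings over ``{A,C,G,T,N}``, one per chromosome.
    seed
        RNG seed the genome was generated with (``None`` for loaded genomes).
    """

    chrom_names: list[str]
    sequences: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.sequences):
            raise ParameterError("chrom_names and sequences must align")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ParameterError("chromosome names must be unique")
        for name, seq in zip(self.chrom_names, self.sequences):
            if len(seq) == 0:
                raise ParameterError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ParameterError(f"chromosome {name!r} has bases {bad}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[self.chrom_names.index(chrom)]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in zip(self.chrom_names, self.sequences)}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def gc_fraction(self, chrom: str | None = None) -> float:
        """Observed G+C fraction over A/C/G/T bases (N excluded)."""
        seqs = [self[chrom]] if chrom is not None else self.sequences
        gc = sum(s.count("G") + s.count("C") for s in seqs)
        at = sum(s.count("A") + s.count("T") for s in seqs)
        return gc / (gc + at)


@dataclass(frozen=True, order=True)
class CnvTruthSegment:
    """A genomic interval carrying an integer copy number (2 = neutral)."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ParameterError(
                f"bad interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number < 0:
            raise ParameterError("copy_number must be non-negative")


@dataclass
class CnvTruth:
    """Validated, sorted copy-number truth covering a genome exactly.

    ``segments`` partition each chromosome: sorted, non-overlapping, abutting,
    spanning ``[0, len)``.  Build with :func:`plant_cnv`.
    """

    segments: list[CnvTruthSegment]

    def copy_number_at(self, chrom: str, pos: int) -> int:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.copy_number
        raise KeyError(f"{chrom}:{pos} not covered by truth")

    def copy_numbers_at(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized lookup; ``chroms`` is an array of chromosome names."""
        out = np.empty(len(positions), dtype=np.int64)
        by_chrom: dict[str, list[CnvTruthSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            starts = np.array([s.start for s in segs])
            cns = np.array([s.copy_number for s in segs])
            sel = chroms == chrom
            idx = np.searchsorted(starts, positions[sel], side="right") - 1
            out[sel] = cns[idx]
        return out


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition site plus forward-strand cut offset.

    ``cut_offset`` is the cut position within the site, ``0 <= offset <=
    len(site)`` (SaqAI ``T^TAA`` has offset 1; Hin1II ``CATG^`` offset 4).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition_site:
            raise ParameterError("recognition_site must be non-empty")
        if set(self.recognition_site) - set("ACGT"):
            raise ParameterError("recognition_site must be over {A,C,G,T}")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ParameterError("cut_offset outside recognition site")


SAQAI = RestrictionEnzyme("SaqAI", "TTAA", 1)
HIN1II = RestrictionEnzyme("Hin1II", "CATG", 4)
ENZYMES = {"SaqAI": SAQAI, "Hin1II": HIN1II}


def _chrom_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    gc_target: float = 0.5,
    seed: int = 0,
    gc_gradient: tuple[float, float] | None = None,
) -> ReferenceGenome:
    """Generate an i.i.d. random genome with a target GC composition.

    Parameters
    ----------
    n_chroms, chrom_length
        Number of chromosomes and their common length (>= 10 kb).
    gc_target
        P(G) + P(C) per base, in (0, 1).  G and C (and A and T) are
        equiprobable within their class.
    gc_gradient
        Optional ``(gc_start, gc_end)``: GC probability varies linearly
        along each chromosome between the two values, overriding
        ``gc_target``.  Useful for stressing GC-bias correction.
    seed
        Deterministic RNG seed.
    """
    if n_chroms < 1:
        raise ParameterError("n_chroms must be >= 1")
    if chrom_length < 10_000:
        raise ParameterError("chrom_length must be >= 10 kb")
    if gc_gradient is None:
        if not 0.0 < gc_target < 1.0:
            raise ParameterError("gc_target must be in (0, 1)")
    else:
        lo, hi = gc_gradient
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ParameterError("gc_gradient endpoints must be in (0, 1)")

    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs: list[str] = []
    for _ in range(n_chroms):
        if gc_gradient is None:
            p_gc = np.full(chrom_length, gc_target)
        else:
            p_gc = np.linspace(gc_gradient[0], gc_gradient[1], chrom_length)
        u = rng.random(chrom_length)
        is_gc = u < p_gc
        # within class, pick the strand-symmetric partner uniformly
        half = rng.random(chrom_length) < 0.5
        codes = np.where(is_gc, np.where(half, 1, 2), np.where(half, 0, 3))
        seqs.append(_BASES[codes].tobytes().decode("ascii"))
    return ReferenceGenome(names, seqs, seed=seed)


def plant_cnv(
    genome: ReferenceGenome, segments: list[CnvTruthSegment]
) -> CnvTruth:
    """Validate user segments and fill unspecified regions at copy number 2.

    Returns a canonical truth: sorted, gap-filled with neutral segments,
    abutting equal-copy-number segments merged.  Overlapping or out-of-bounds
    segments raise a validation error listing the offenders.
    """
    lengths = genome.lengths
    offenders: list[str] = []
    by_chrom: dict[str, list[CnvTruthSegment]] = {c: [] for c in genome.chrom_names}
    for seg in segments:
        if seg.chrom not in lengths:
            offenders.append(f"unknown chromosome: {seg}")
            continue
        if seg.end > lengths[seg.chrom]:
            offenders.append(f"out of bounds: {seg}")
            continue
        by_chrom[seg.chrom].append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort()
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                offenders.append(f"overlap: {a} / {b}")
    if offenders:
        raise ParameterError("invalid CNV segments:\n" + "\n".join(offenders))

    out: list[CnvTruthSegment] = []
    for chrom in genome.chrom_names:
        length = lengths[chrom]
        filled: list[CnvTruthSegment] = []
        pos = 0
        for seg in by_chrom[chrom]:
            if seg.start > pos:
                filled.append(CnvTruthSegment(chrom, pos, seg.start, 2))
            filled.append(seg)
            pos = seg.end
        if pos < length:
            filled.append(CnvTruthSegment(chrom, pos, length, 2))
        # merge abutting equal-CN segments
        merged: list[CnvTruthSegment] = []
        for seg in filled:
            if merged and merged[-1].copy_number == seg.copy_number:
                prev = merged.pop()
                seg = CnvTruthSegment(chrom, prev.start, seg.end, seg.copy_number)
            merged.append(seg)
        out.extend(merged)
    return CnvTruth(out)


def find_sites(seq: str, site: str) -> np.ndarray:
    """All start positions of exact (possibly overlapping) site occurrences."""
    arr = _chrom_array(seq)
    pat = _chrom_array(site)
    if len(arr) < len(pat):
        return np.empty(0, dtype=np.int64)
    hits = arr[: len(arr) - len(pat) + 1] == pat[0]
    for i in range(1, len(pat)):
        hits &= arr[i : len(arr) - len(pat) + 1 + i] == pat[i]
    return np.flatnonzero(hits).astype(np.int64)


def digest(
    genome: ReferenceGenome, enzyme: RestrictionEnzyme
) -> dict[str, np.ndarray]:
    """In-silico digestion: fragment intervals per chromosome.

    Returns ``{chrom: (n_fragments, 2) int64 array}`` of half-open intervals
    between consecutive cuts (cut coordinate = site start + cut_offset),
    including the two chromosome-end pieces.  A site-free chromosome yields a
    single fragment spanning it.  Concatenating a chromosome's fragments in
    order reproduces the chromosome exactly.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, seq in zip(genome.chrom_names, genome.sequences):
        cuts = find_sites(seq, enzyme.recognition_site) + enzyme.cut_offset
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        bounds = np.concatenate(([0], np.unique(cuts), [len(seq)]))
        out[chrom] = np.column_stack((bounds[:-1], bounds[1:]))
    return out


def fragment_length_stats(
    fragments: dict[str, np.ndarray],
) -> tuple[float, float, np.ndarray]:
    """Mean, median and 1-bp histogram of fragment lengths across chromosomes.

    The histogram is an integer array ``h`` with ``h[L]`` = number of
    fragments of length ``L`` (index 0 unused).
    """
    lens = np.concatenate(
        [iv[:, 1] - iv[:, 0] for iv in fragments.values() if len(iv)]
        or [np.empty(0, dtype=np.int64)]
    )
    if lens.size == 0:
        raise ParameterError("no fragments given")
    hist = np.bincount(lens)
    return float(lens.mean()), float(np.median(lens)), hist
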