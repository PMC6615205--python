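"""Split-read fragment mapping by seed-and-extend alignment.

Concatenated-fragment reads contain many short molecules, each originating
from a different genomic locus.  Mapping therefore splits a read into
fragments: short exact seed hits cluster on reference diagonals, nearby
co-linear clusters are chained, and each chain is extended with a local
affine-gap Smith-Waterman alignment.  A fragment is reported only when its
local alignment score reaches ``min_report_score``.

The scoring constants default to the regime tuned for this read type
(match +4, mismatch 10, gap open 6, gap extend 3, seed length 12, minimum
chain weight 12, report threshold 120; a gap of length k costs
``gap_open + k*gap_extend``).  The seed index is a sorted k-mer table rather
than an FM-index: it is exact, simple, and adequate for the tens-of-megabase
references this toolkit targets.

Uniqueness: a fragment is flagged ``is_unique`` when its best placement
strictly outscores every alternative placement overlapping the same part of
the read; only unique fragments are counted by the CNV pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import ParameterError, ReferenceGenome
from .simulate import SmurfRead, reverse_complement

__all__ = [
    "ScoringScheme",
    "FragmentAlignment",
    "SeedIndex",
    "build_index",
    "seed_and_chain",
    "extend",
    "map_read",
    "map_reads",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring constants for the split mapper."""

    match: int = 4
    mismatch_penalty: int = 10
    gap_open: int = 6
    gap_extend: int = 3
    min_seed_len: int = 12
    min_chain_weight: int = 12
    min_report_score: int = 120
    chain_band: int = 100          # max diagonal drift within a chain (bp)
    chain_max_gap: int = 500       # max read-space gap between joined seeds (bp)
    chain_overlap_frac: float = 0.5   # chains overlapping more on the read: lighter dropped
    frag_overlap_frac: float = 0.2    # fragment reports overlapping more: lower score dropped
    extend_margin: int = 50           # window slack around a chain for extension
    extend_band_slack: int = 40       # diagonal slack around chain seeds in the DP band

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ParameterError("penalties must be >= 0")
        if self.min_report_score <= 0:
            raise ParameterError("min_report_score must be > 0")

    def gap_cost(self, k: int) -> int:
        return self.gap_open + k * self.gap_extend


@dataclass
class FragmentAlignment:
    """One mapped fragment of a read (all coordinates 0-based half-open)."""

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    score: int
    is_unique: bool = True

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class Chain:
    """A cluster of co-linear seeds on one (chromosome, strand)."""

    chrom: str
    strand: str
    # coordinates in strand-adjusted read space (i.e. on the read or its
    # reverse complement, matching the forward reference)
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    weight: int
    diag: int
    seeds: list[tuple[int, int, int]] = field(default_factory=list)  # (read, ref, len)


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and start positions (N-containing excluded)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    bad = (codes >= 4).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    vals = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for i in range(k):
        vals = (vals << np.uint64(2)) | c[i : i + n]
    pos = np.flatnonzero(valid).astype(np.int64)
    return vals[pos], pos


class SeedIndex:
    """Sorted exact k-mer lookup table over a reference genome."""

    def __init__(self, genome: ReferenceGenome, k: int):
        if k < 8:
            raise ParameterError("k must be >= 8")
        if k > 31:
            raise ParameterError("k must be <= 31 (2-bit packed)")
        if max(genome.lengths.values()) < k:
            raise ParameterError("genome shorter than k")
        self.genome = genome
        self.k = k
        codes_all: list[np.ndarray] = []
        pos_all: list[np.ndarray] = []
        offsets = [0]
        for seq in genome.sequences:
            c = _encode(seq)
            vals, pos = _kmer_codes(c, k)
            codes_all.append(vals)
            pos_all.append(pos + offsets[-1])
            offsets.append(offsets[-1] + len(seq))
        self.offsets = np.array(offsets, dtype=np.int64)  # chrom start in global coords
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]
        self._seq_codes = [_encode(s) for s in genome.sequences]

    def chrom_of(self, gpos: np.ndarray) -> np.ndarray:
        """Chromosome index for global positions."""
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """Reference placements of ``kmer``: forward-strand matches as '+',
        positions whose forward k-mer is the reverse complement as '-'."""
        out: list[tuple[str, int, str]] = []
        for query, strand in ((kmer, "+"), (reverse_complement(kmer), "-")):
            vals, _ = _kmer_codes(_encode(query), self.k)
            if vals.size == 0:
                continue
            lo = np.searchsorted(self.sorted_codes, vals[0], side="left")
            hi = np.searchsorted(self.sorted_codes, vals[0], side="right")
            for g in self.sorted_pos[lo:hi]:
                ci = int(self.chrom_of(np.array([g]))[0])
                out.append(
                    (self.genome.chrom_names[ci], int(g - self.offsets[ci]), strand)
                )
        return sorted(set(out))

    def hits(self, codes: np.ndarray, pos: np.ndarray, max_hits: int = 64):
        """Vectorized: (read_pos, global_ref_pos) pairs for exact k-mer hits.

        k-mers with more than ``max_hits`` reference placements are skipped
        (repeat guard)."""
        order = np.argsort(codes, kind="stable")  # sorted queries scan faster
        sc = codes[order]
        lo = np.searchsorted(self.sorted_codes, sc, side="left")
        hi = np.searchsorted(self.sorted_codes, sc, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_hits)
        lo, pos_k = lo[keep], pos[order[keep]]
        counts = counts[keep]
        if len(lo) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        read_pos = np.repeat(pos_k, counts)
        # ragged [lo_i, lo_i + counts_i) expansion without a Python loop
        ends = np.cumsum(counts)
        idx = np.arange(ends[-1]) + np.repeat(lo - np.concatenate(([0], ends[:-1])), counts)
        return read_pos, self.sorted_pos[idx]


def build_index(genome: ReferenceGenome, k: int = 12) -> SeedIndex:
    """Build the exact-match seed index (both strands resolvable at query)."""
    return SeedIndex(genome, k)


def _merge_seeds(read_pos: np.ndarray, ref_pos: np.ndarray, k: int):
    """Collapse runs of consecutive same-diagonal k-mer hits into maximal
    exact-match seeds; returns (read_start, ref_start, length) arrays."""
    empty = np.empty(0, dtype=np.int64)
    if len(read_pos) == 0:
        return empty, empty, empty
    diag = ref_pos - read_pos
    order = np.lexsort((read_pos, diag))
    rp, gp, dg = read_pos[order], ref_pos[order], diag[order]
    new = np.empty(len(rp), dtype=bool)
    new[0] = True
    new[1:] = (dg[1:] != dg[:-1]) | (rp[1:] != rp[:-1] + 1)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], len(rp))
    return rp[starts], gp[starts], rp[ends - 1] - rp[starts] + k


def seed_and_chain(
    read: SmurfRead | str, index: SeedIndex, scoring: ScoringScheme = ScoringScheme()
) -> list[Chain]:
    """Find seeds on both strands and group co-linear ones into chains.

    Seeds are maximal exact matches of at least ``min_seed_len``.  A seed
    joins a chain when it is on the same chromosome and strand, within
    ``chain_band`` of the chain's diagonal corridor, and within
    ``chain_max_gap`` of the chain on the read.  Chains lighter than
    ``min_chain_weight`` are dropped; of chains overlapping more than
    ``chain_overlap_frac`` on the read, only strictly lighter ones are
    dropped (equal-weight alternatives survive so downstream uniqueness
    flags can see them).
    """
    kept, _, _, _ = _chain_candidates(read, index, scoring)
    return kept


def _NO_CHAINS():
    e = np.empty(0, dtype=np.int64)
    return [], e, e, (lambda indices: [])


def _chain_candidates(read: SmurfRead | str, index: SeedIndex, scoring: ScoringScheme):
    """Chains passing the weight filter, split by the greedy read-overlap
    suppression rule.

    Returns ``(kept, drop_a0, drop_a1, build_dropped)``: the kept chains
    (sorted by original-read start), the suppressed chains' original-read
    spans, and a callable materializing suppressed chains by index (they are
    numerous and usually never needed)."""
    seq = read.sequence if isinstance(read, SmurfRead) else read
    k = scoring.min_seed_len
    band = scoring.chain_band
    if len(seq) < k:
        return _NO_CHAINS()
    L = len(seq)
    # per-group arrays accumulated across strands and chromosomes
    groups: list[tuple] = []  # (chrom_idx, strand, seed arrays slice info)
    g_read0: list[np.ndarray] = []
    g_read1: list[np.ndarray] = []
    g_ref0: list[np.ndarray] = []
    g_ref1: list[np.ndarray] = []
    g_weight: list[np.ndarray] = []
    g_diag0: list[np.ndarray] = []
    g_drift: list[np.ndarray] = []
    g_meta: list[tuple] = []  # (strand, chrom_idx, rp, gp, ln, starts, ends)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        codes, pos = _kmer_codes(_encode(s), k)
        rp_all, gp_all = index.hits(codes, pos)
        if len(rp_all) == 0:
            continue
        ci = index.chrom_of(gp_all)
        for chrom_idx in np.unique(ci):
            sel = ci == chrom_idx
            rp, gp, ln = _merge_seeds(
                rp_all[sel], gp_all[sel] - index.offsets[chrom_idx], k
            )
            # group seeds into chains: sort by diagonal and split where the
            # diagonal jumps by more than the band (co-linearity within an
            # indel-tolerant diagonal corridor), then split again where
            # consecutive seeds are further apart on the read than
            # chain_max_gap (a distant stray seed on a similar diagonal must
            # not bridge unrelated fragments)
            diag = gp - rp
            order = np.argsort(diag, kind="stable")
            dgs = diag[order]
            gid = np.concatenate(
                ([0], np.cumsum(np.diff(dgs) > band))
            )
            order2 = np.lexsort((rp[order], gid))
            rps, gps, lns = rp[order][order2], gp[order][order2], ln[order][order2]
            dgs = dgs[order2]
            gid = gid[order2]
            gap_brk = np.empty(len(rps), dtype=bool)
            gap_brk[0] = True
            gap_brk[1:] = (gid[1:] != gid[:-1]) | (
                rps[1:] - (rps[:-1] + lns[:-1]) > scoring.chain_max_gap
            )
            starts = np.flatnonzero(gap_brk)
            ends = np.append(starts[1:], len(rps))
            g_read0.append(np.minimum.reduceat(rps, starts))
            g_read1.append(np.maximum.reduceat(rps + lns, starts))
            g_ref0.append(np.minimum.reduceat(gps, starts))
            g_ref1.append(np.maximum.reduceat(gps + lns, starts))
            g_weight.append(np.add.reduceat(lns, starts))
            d0 = np.minimum.reduceat(dgs, starts)
            g_diag0.append(d0)
            g_drift.append(np.maximum.reduceat(dgs, starts) - d0)
            g_meta.append((strand, int(chrom_idx), rps, gps, lns, starts, ends))

    if not g_meta:
        return _NO_CHAINS()
    read0 = np.concatenate(g_read0)
    read1 = np.concatenate(g_read1)
    ref0 = np.concatenate(g_ref0)
    ref1 = np.concatenate(g_ref1)
    weight = np.concatenate(g_weight)
    diag0 = np.concatenate(g_diag0)
    drift = np.concatenate(g_drift)
    strands = np.concatenate(
        [np.full(len(a), 0 if m[0] == "+" else 1, dtype=np.int8)
         for a, m in zip(g_read0, g_meta)]
    )
    chrom_ids = np.concatenate(
        [np.full(len(a), m[1], dtype=np.int64) for a, m in zip(g_read0, g_meta)]
    )
    block = np.concatenate(
        [np.full(len(a), bi, dtype=np.int64) for bi, a in enumerate(g_read0)]
    )
    within = np.concatenate([np.arange(len(a)) for a in g_read0])

    ok = weight >= scoring.min_chain_weight
    # original-read-coordinate spans (reverse-strand chains live in rc space)
    a0 = np.where(strands == 0, read0, L - read1)
    a1 = np.where(strands == 0, read1, L - read0)
    # drop strictly lighter chains buried (> chain_overlap_frac of the
    # shorter span) under heavier ones on the read; equal-weight alternatives
    # survive so downstream uniqueness flags can see them
    idx = np.flatnonzero(ok)
    order = idx[np.lexsort((ref0[idx], chrom_ids[idx], -weight[idx]))]
    keep = _suppress_spans(
        a0[order], a1[order], weight[order], scoring.chain_overlap_frac
    )
    kept_idx = order[keep]
    kept_idx = kept_idx[np.argsort(a0[kept_idx], kind="stable")]
    drop_idx = order[~keep]
    drop_idx = drop_idx[np.argsort(a0[drop_idx], kind="stable")]

    def build(gi: int) -> Chain:
        strand, chrom_idx, rps, gps, lns, starts, ends = g_meta[block[gi]]
        s0, s1 = starts[within[gi]], ends[within[gi]]
        members = sorted(
            zip(rps[s0:s1].tolist(), gps[s0:s1].tolist(), lns[s0:s1].tolist())
        )
        return Chain(
            chrom=index.genome.chrom_names[chrom_idx],
            strand=strand,
            read_start=int(read0[gi]),
            read_end=int(read1[gi]),
            ref_start=int(ref0[gi]),
            ref_end=int(ref1[gi]),
            weight=int(weight[gi]),
            diag=int(diag0[gi]),
            seeds=members,
        )

    def build_dropped(indices: np.ndarray) -> list[Chain]:
        return [build(gi) for gi in drop_idx[indices]]

    return (
        [build(gi) for gi in kept_idx],
        a0[drop_idx],
        a1[drop_idx],
        build_dropped,
    )


@njit(cache=True)
def _suppress_spans(a0, a1, w, frac):
    """Greedy span suppression: entries are visited in priority order; an
    entry is dropped when it overlaps an already-kept span by more than
    ``frac`` of the shorter one and is strictly lighter."""
    n = len(a0)
    keep = np.zeros(n, dtype=np.bool_)
    kb0 = np.empty(n, dtype=np.int64)
    kb1 = np.empty(n, dtype=np.int64)
    kw = np.empty(n, dtype=np.int64)
    m = 0
    for i in range(n):
        drop = False
        li = a1[i] - a0[i]
        for j in range(m):
            ov = min(a1[i], kb1[j]) - max(a0[i], kb0[j])
            lj = kb1[j] - kb0[j]
            if ov > frac * min(li, lj) and w[i] < kw[j]:
                drop = True
                break
        if not drop:
            keep[i] = True
            kb0[m] = a0[i]
            kb1[m] = a1[i]
            kw[m] = w[i]
            m += 1
    return keep


@njit(cache=True)
def _sw_best_end(q, t, dlo, dhi, match, mismatch, gap_open, gap_ext):
    """Banded local affine SW; returns (best, end_i, end_j), 1-based end
    coordinates of the best local alignment.

    The band admits cells with ``dlo <= j - i <= dhi``.  Out-of-band cells
    are treated as fresh alignment starts (score 0, no open gap), which is a
    lower bound on the true cell value, so a banded score can never exceed
    the unbanded one; with ``dlo = -len(q), dhi = len(t)`` the recursion is
    the exact full Smith-Waterman.  Single rolling row, no allocation in the
    inner loop."""
    n, m = len(q), len(t)
    NEG = -(10 ** 9)
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > m:
            jhi = m
        if jlo > jhi:
            continue
        qi = q[i - 1]
        diag = H[jlo - 1]  # row i-1 value (in band last row, or initial 0)
        hleft = 0          # H[i][jlo-1] is out of band: fresh-start bound
        F = NEG
        for j in range(jlo, jhi + 1):
            hup = H[j]
            e = E[j] - gap_ext
            o = hup - gap_open - gap_ext
            if o > e:
                e = o
            E[j] = e
            f = F - gap_ext
            o = hleft - gap_open - gap_ext
            if o > f:
                f = o
            F = f
            if qi == t[j - 1] and qi < 4:
                h = diag + match
            else:
                h = diag - mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[j] = h
            diag = hup
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _sw_batch(qcat, qoff, tcat, toff, dlo, dhi,
              match, mismatch, gap_open, gap_ext):
    """Forward banded local-SW pass over many windows in one jitted call."""
    nb = len(qoff) - 1
    best = np.zeros(nb, dtype=np.int64)
    bi = np.zeros(nb, dtype=np.int64)
    bj = np.zeros(nb, dtype=np.int64)
    for b in range(nb):
        sc, i, j = _sw_best_end(
            qcat[qoff[b] : qoff[b + 1]],
            tcat[toff[b] : toff[b + 1]],
            dlo[b], dhi[b],
            match, mismatch, gap_open, gap_ext,
        )
        best[b] = sc
        bi[b] = i
        bj[b] = j
    return best, bi, bj


def _chain_window(
    chain: Chain, read_len: int, ref_len: int, scoring: ScoringScheme
) -> tuple[int, int, int, int, int, int]:
    """Extension window and band for a chain.

    Returns ``(q0, q1, t0, t1, dlo, dhi)``: window bounds in strand-adjusted
    read space / chromosome space, and the admitted diagonal corridor
    ``dlo <= j - i <= dhi`` in window coordinates (the chain's seed diagonals
    widened by ``extend_band_slack`` for gaps opened during extension)."""
    m = scoring.extend_margin
    drift = (
        max(abs((g - r) - chain.diag) for r, g, _ in chain.seeds)
        if chain.seeds
        else 0
    )
    q0 = max(0, chain.read_start - m)
    q1 = min(read_len, chain.read_end + m)
    t0 = max(0, chain.ref_start - m - drift - 10)
    t1 = min(ref_len, chain.ref_end + m + drift + 10)
    if chain.seeds:
        wds = [(g - t0) - (r - q0) for r, g, _ in chain.seeds]
        dlo = min(wds) - scoring.extend_band_slack
        dhi = max(wds) + scoring.extend_band_slack
    else:
        dlo, dhi = -(q1 - q0), t1 - t0
    return q0, q1, t0, t1, dlo, dhi


def _sw_local(q: np.ndarray, t: np.ndarray, sc: ScoringScheme,
              dlo: int | None = None, dhi: int | None = None):
    """Best local alignment (score, q_start, q_end, t_start, t_end) via a
    forward pass for the end and a reverse pass for the start."""
    if dlo is None:
        dlo = -len(q)
    if dhi is None:
        dhi = len(t)
    best, bi, bj = _sw_best_end(
        q, t, dlo, dhi, sc.match, sc.mismatch_penalty, sc.gap_open, sc.gap_extend
    )
    if best == 0:
        return 0, 0, 0, 0, 0
    rbest, ri, rj = _sw_best_end(
        q[:bi][::-1].copy(), t[:bj][::-1].copy(),
        (bj - bi) - dhi, (bj - bi) - dlo,
        sc.match, sc.mismatch_penalty, sc.gap_open, sc.gap_extend,
    )
    return best, bi - ri, bi, bj - rj, bj


def extend(
    chain: Chain,
    read: SmurfRead | str,
    genome: ReferenceGenome,
    scoring: ScoringScheme = ScoringScheme(),
    read_id: str = "",
) -> FragmentAlignment | None:
    """Extend a chain with local Smith-Waterman; report if score reaches
    ``min_report_score``, else ``None``.

    The DP runs over a window covering the chain plus ``extend_margin``
    slack (reference side additionally padded by the chain's diagonal
    drift), banded to the chain's diagonal corridor widened by
    ``extend_band_slack``.
    """
    seq = read.sequence if isinstance(read, SmurfRead) else read
    rid = read.read_id if isinstance(read, SmurfRead) else read_id
    s = seq if chain.strand == "+" else reverse_complement(seq)
    L = len(s)
    ref_seq = genome[chain.chrom]
    q0, q1, t0, t1, dlo, dhi = _chain_window(chain, L, len(ref_seq), scoring)
    q = _encode(s[q0:q1])
    t = _encode(ref_seq[t0:t1])
    score, qs, qe, ts, te = _sw_local(q, t, scoring, dlo, dhi)
    if score < scoring.min_report_score:
        return None
    rs, re = q0 + qs, q0 + qe  # strand-adjusted read coords
    if chain.strand == "-":
        rs, re = L - re, L - rs
    return FragmentAlignment(
        read_id=rid,
        read_start=rs,
        read_end=re,
        chrom=chain.chrom,
        ref_start=t0 + ts,
        ref_end=t0 + te,
        strand=chain.strand,
        score=int(score),
    )


def _extend_batch(
    chains: list[Chain],
    read: SmurfRead | str,
    genome: ReferenceGenome,
    scoring: ScoringScheme,
    read_id: str = "",
) -> list[FragmentAlignment]:
    """Extend many chains with two batched DP passes (identical results to
    calling :func:`extend` per chain, minus per-call dispatch overhead)."""
    if not chains:
        return []
    seq = read.sequence if isinstance(read, SmurfRead) else read
    rid = read.read_id if isinstance(read, SmurfRead) else read_id
    enc = {"+": _encode(seq), "-": _encode(reverse_complement(seq))}
    L = len(seq)
    qs_parts, ts_parts, windows = [], [], []
    for ch in chains:
        ref_seq = genome[ch.chrom]
        q0, q1, t0, t1, dlo, dhi = _chain_window(ch, L, len(ref_seq), scoring)
        qs_parts.append(enc[ch.strand][q0:q1])
        ts_parts.append(_encode(ref_seq[t0:t1]))
        windows.append((q0, q1, t0, t1, dlo, dhi))
    qoff = np.concatenate(([0], np.cumsum([len(a) for a in qs_parts])))
    toff = np.concatenate(([0], np.cumsum([len(a) for a in ts_parts])))
    qcat = np.concatenate(qs_parts)
    tcat = np.concatenate(ts_parts)
    dlo_arr = np.array([w[4] for w in windows], dtype=np.int64)
    dhi_arr = np.array([w[5] for w in windows], dtype=np.int64)
    best, bi, bj = _sw_batch(
        qcat, qoff, tcat, toff, dlo_arr, dhi_arr,
        scoring.match, scoring.mismatch_penalty,
        scoring.gap_open, scoring.gap_extend,
    )
    hit = np.flatnonzero(best >= scoring.min_report_score)
    if len(hit) == 0:
        return []
    # reverse pass (alignment starts) only for reported windows
    rq_parts = [qcat[qoff[h] : qoff[h] + bi[h]][::-1] for h in hit]
    rt_parts = [tcat[toff[h] : toff[h] + bj[h]][::-1] for h in hit]
    rqoff = np.concatenate(([0], np.cumsum([len(a) for a in rq_parts])))
    rtoff = np.concatenate(([0], np.cumsum([len(a) for a in rt_parts])))
    rdlo = np.array([(bj[h] - bi[h]) - dhi_arr[h] for h in hit], dtype=np.int64)
    rdhi = np.array([(bj[h] - bi[h]) - dlo_arr[h] for h in hit], dtype=np.int64)
    rbest, ri, rj = _sw_batch(
        np.concatenate(rq_parts), rqoff, np.concatenate(rt_parts), rtoff,
        rdlo, rdhi,
        scoring.match, scoring.mismatch_penalty,
        scoring.gap_open, scoring.gap_extend,
    )
    out: list[FragmentAlignment] = []
    for n, h in enumerate(hit):
        ch = chains[h]
        q0, _, t0, _, _, _ = windows[h]
        qs, qe = int(bi[h] - ri[n]), int(bi[h])
        ts, te = int(bj[h] - rj[n]), int(bj[h])
        rs, re = q0 + qs, q0 + qe
        if ch.strand == "-":
            rs, re = L - re, L - rs
        out.append(
            FragmentAlignment(
                read_id=rid, read_start=rs, read_end=re, chrom=ch.chrom,
                ref_start=t0 + ts, ref_end=t0 + te, strand=ch.strand,
                score=int(best[h]),
            )
        )
    return out


def map_read(
    read: SmurfRead | str,
    index: SeedIndex,
    scoring: ScoringScheme = ScoringScheme(),
    read_id: str = "",
) -> list[FragmentAlignment]:
    """Full pipeline for one read: seed, chain, extend, resolve overlaps.

    Overlapping fragment reports on the read are resolved greedily by score
    (ties broken by lowest ``(chrom, ref_start)``): a report overlapping a
    kept one by more than ``frag_overlap_frac`` of the shorter is removed.
    ``is_unique`` is False when any *other* candidate overlapping at least
    half of the fragment's read interval scores as high.  Output sorted by
    ``read_start``.

    Suppressed chains (buried under a heavier chain's span) are rescued and
    extended when the winners' actual alignments leave their read interval
    mostly uncovered — a chain's span can be inflated by a stray co-diagonal
    seed, and the fragment underneath it must still be reported.
    """
    chains, drop_a0, drop_a1, build_dropped = _chain_candidates(read, index, scoring)
    cands = _extend_batch(chains, read, index.genome, scoring, read_id=read_id)
    if len(drop_a0) and cands:
        seq_len = len(read.sequence if isinstance(read, SmurfRead) else read)
        delta = np.zeros(seq_len + 1, dtype=np.int32)
        for a in cands:
            delta[a.read_start] += 1
            delta[a.read_end] -= 1
        covered = np.cumsum(delta)[:-1] > 0
        cum = np.concatenate(([0], np.cumsum(covered)))
        uncovered = (cum[drop_a1] - cum[drop_a0]) <= 0.5 * (drop_a1 - drop_a0)
        if uncovered.any():
            rescue = build_dropped(np.flatnonzero(uncovered))
            cands += _extend_batch(
                rescue, read, index.genome, scoring, read_id=read_id
            )
    cands.sort(key=lambda a: (-a.score, a.chrom, a.ref_start, a.read_start))
    kept: list[FragmentAlignment] = []
    for a in cands:
        ok = True
        for b in kept:
            ov = min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
            if ov > scoring.frag_overlap_frac * min(a.read_span, b.read_span):
                ok = False
                break
        if ok:
            kept.append(a)
    for a in kept:
        for b in cands:
            if b is a:
                continue
            ov = min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
            if ov >= 0.5 * a.read_span and b.score >= a.score:
                a.is_unique = False
                break
    kept.sort(key=lambda x: x.read_start)
    return kept


def map_reads(
    reads: list[SmurfRead],
    index: SeedIndex,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[FragmentAlignment]:
    """Map a batch of reads; concatenated per-read results."""
    out: list[FragmentAlignment] = []
    for r in reads:
        out.extend(map_read(r, index, scoring))
    return out


# -- full-matrix variant with traceback (used for path re-scoring and SAM) --

@njit(cache=True)
def _sw_matrices(q, t, match, mismatch, gap_open, gap_ext):
    n, m = len(q), len(t)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i - 1][j] - gap_ext
            o = H[i - 1][j] - gap_open - gap_ext
            E[i][j] = e if e > o else o
            f = F[i][j - 1] - gap_ext
            o = H[i][j - 1] - gap_open - gap_ext
            F[i][j] = f if f > o else o
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                h = H[i - 1][j - 1] + match
            else:
                h = H[i - 1][j - 1] - mismatch
            if E[i][j] > h:
                h = E[i][j]
            if F[i][j] > h:
                h = F[i][j]
            if h < 0:
                h = 0
            H[i][j] = h
    return H, E, F


def sw_align_path(
    q_seq: str, t_seq: str, scoring: ScoringScheme = ScoringScheme()
) -> tuple[int, int, int, int, int, list[str]]:
    """Best local alignment with an explicit operation path.

    Returns ``(score, q_start, q_end, t_start, t_end, ops)`` where ops are
    'M' (match), 'X' (mismatch), 'I' (base in query only), 'D' (base in
    target only), in query order.  Intended for path re-scoring checks and
    CIGAR export; quadratic memory, use on fragment-sized sequences.
    """
    q, t = _encode(q_seq), _encode(t_seq)
    sc = scoring
    H, E, F = _sw_matrices(
        q, t, sc.match, sc.mismatch_penalty, sc.gap_open, sc.gap_extend
    )
    best = int(H.max())
    if best == 0:
        return 0, 0, 0, 0, 0, []
    bi, bj = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(bi), int(bj)
    ops: list[str] = []
    state = "H"
    while H[i][j] > 0 or state != "H":
        if state == "H":
            if H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                match = q[i - 1] == t[j - 1] and q[i - 1] < 4
                ops.append("M" if match else "X")
                i, j = i - 1, j - 1
        elif state == "E":  # gap in target: consume query base
            ops.append("I")
            prev_open = H[i - 1][j] - sc.gap_open - sc.gap_extend
            state = "H" if E[i][j] == prev_open else "E"
            i -= 1
        else:  # F: gap in query: consume target base
            ops.append("D")
            prev_open = H[i][j - 1] - sc.gap_open - sc.gap_extend
            state = "H" if F[i][j] == prev_open else "F"
            j -= 1
    ops.reverse()
    return best, i, int(bi), j, int(bj), ops


def score_path(ops: list[str], scoring: ScoringScheme = ScoringScheme()) -> int:
    """Re-score an alignment path under the scoring scheme (gap of length k
    costs ``gap_open + k*gap_extend``)."""
    score = 0
    run = None
    for op in ops + [None]:
        if op in ("I", "D"):
            if run == op:
                score -= scoring.gap_extend
            else:
                score -= scoring.gap_open + scoring.gap_extend
            run = op
        else:
            if op == "M":
                score += scoring.match
            elif op == "X":
                score -= scoring.mismatch_penalty
            run = None
    return score
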