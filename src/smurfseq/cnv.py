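"""Read-count copy-number profiling from uniquely mapped fragments.

The pipeline follows the standard low-coverage sparse-sequencing recipe:

1. split the genome into variable-width bins each containing an equal number
   of *uniquely mappable* positions (equalizing expected counts under
   uniform coverage);
2. count uniquely mapped fragments per bin by reference midpoint;
3. mask "bad" bins with spuriously high counts (robust median + MAD rule);
4. correct GC-content bias by subtracting a LOWESS fit of count on bin GC;
5. normalize to bin ratios (corrected count / mean over unmasked bins);
6. segment the ratios per chromosome with circular binary segmentation
   (CBS), assessed by permutation;
7. merge spurious (short or shallow) segments;
8. call each bin amplified / neutral / deleted from its segment mean using
   the 1.25 / 0.8 cutoffs (boundary inclusive).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .align import FragmentAlignment
from .genome import ParameterError, ReferenceGenome

__all__ = [
    "GenomicBin",
    "Segment",
    "CnvProfile",
    "compute_mappability",
    "make_bins",
    "count_fragments",
    "mask_bad_bins",
    "gc_correct",
    "segment_cbs",
    "remove_spurious_segments",
    "call_events",
    "profile",
    "AMP_CUTOFF",
    "DEL_CUTOFF",
]

AMP_CUTOFF = 1.25
DEL_CUTOFF = 0.8

STATE_AMPLIFIED = "amplified"
STATE_NEUTRAL = "neutral"
STATE_DELETED = "deleted"


@dataclass
class GenomicBin:
    chrom: str
    start: int
    end: int
    n_mappable: int
    gc: float
    raw_count: int = 0
    corrected_count: float = 0.0
    ratio: float = 0.0
    masked: bool = False


@dataclass
class Segment:
    """Inclusive run of unmasked-bin indices with its mean ratio."""

    first_bin: int
    last_bin: int
    mean_ratio: float

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1


@dataclass
class CnvProfile:
    """Bins + segmentation + per-bin event calls, with provenance."""

    bins: list[GenomicBin]
    segments: list[Segment]          # indices into the unmasked-bin sequence
    events: list[str]                # state per unmasked bin
    unmasked_index: np.ndarray       # bin index (into .bins) per unmasked bin
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                dict(
                    chrom=b.chrom, start=b.start, end=b.end,
                    n_mappable=b.n_mappable, gc=b.gc, raw_count=b.raw_count,
                    corrected_count=b.corrected_count, ratio=b.ratio,
                    masked=b.masked,
                )
                for b in self.bins
            ]
        )
        df["segment_mean"] = np.nan
        df["state"] = "masked"
        seg_mean = np.empty(len(self.unmasked_index))
        for seg in self.segments:
            seg_mean[seg.first_bin : seg.last_bin + 1] = seg.mean_ratio
        df.loc[self.unmasked_index, "segment_mean"] = seg_mean
        df.loc[self.unmasked_index, "state"] = self.events
        return df

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            idx = self.unmasked_index[seg.first_bin : seg.last_bin + 1]
            first, last = self.bins[idx[0]], self.bins[idx[-1]]
            rows.append(
                dict(chrom=first.chrom, start=first.start, end=last.end,
                     n_bins=seg.n_bins, mean_ratio=seg.mean_ratio)
            )
        return pd.DataFrame(rows)


def compute_mappability(
    genome: ReferenceGenome, probe_len: int = 40
) -> dict[str, np.ndarray]:
    """Per-position unique-mappability flags.

    Position ``p`` of a chromosome is uniquely mappable iff the
    ``probe_len``-mer starting there contains no N and occurs exactly once
    in the genome counting both strands.  Returns a boolean array per
    chromosome (positions within ``probe_len-1`` of the end are False).
    """
    if probe_len < 20:
        raise ParameterError("probe_len must be >= 20")
    if probe_len > min(genome.lengths.values()):
        raise ParameterError("probe_len longer than a chromosome")
    if probe_len > 64:
        raise ParameterError("probe_len must be <= 64")

    fwd_keys, rc_keys, valids = [], [], []
    for seq in genome.sequences:
        codes = _encode_acgtn(seq)
        n = len(codes) - probe_len + 1
        bad = (codes >= 4).astype(np.int64)
        cbad = np.concatenate(([0], np.cumsum(bad)))
        valid = (cbad[probe_len:] - cbad[:-probe_len]) == 0
        safe = np.where(codes >= 4, 0, codes).astype(np.uint64)
        rc_safe = (np.uint64(3) - safe)[::-1]
        fwd_keys.append(_probe_keys(safe, probe_len, n))
        # rc probe at position p = forward probe of the reverse-complemented
        # sequence at the mirrored position
        rc_keys.append(_probe_keys(rc_safe, probe_len, n)[::-1])
        valids.append(valid)

    fwd = np.concatenate(fwd_keys)
    rc = np.concatenate(rc_keys)
    valid = np.concatenate(valids)
    # count occurrences of each forward probe among all (fwd + rc) probes of
    # valid positions
    pool = np.sort(np.concatenate([fwd[valid], rc[valid]]))
    lo = np.searchsorted(pool, fwd, side="left")
    hi = np.searchsorted(pool, fwd, side="right")
    unique = valid & ((hi - lo) == 1)

    out: dict[str, np.ndarray] = {}
    off = 0
    for chrom, seq in zip(genome.chrom_names, genome.sequences):
        n = len(seq) - probe_len + 1
        flags = np.zeros(len(seq), dtype=bool)
        flags[:n] = unique[off : off + n]
        out[chrom] = flags
        off += n
    return out


def _encode_acgtn(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _probe_keys(codes: np.ndarray, k: int, n: int) -> np.ndarray:
    """64-bit key per length-k window.

    Probes up to 32 bases are 2-bit packed exactly; longer probes mix the
    two packed halves with a Fibonacci-hash multiplier, so equal probes
    always share a key and distinct probes collide with probability ~2^-64
    per pair (negligible at this toolkit's genome sizes)."""
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    w = np.zeros(n, dtype=np.uint64)
    for i in range(min(k, 32)):
        w = (w << np.uint64(2)) | c[i : i + n]
    if k > 32:
        w2 = np.zeros(n, dtype=np.uint64)
        for i in range(32, k):
            w2 = (w2 << np.uint64(2)) | c[i : i + n]
        w = w * np.uint64(0x9E3779B97F4A7C15) ^ w2
    return w


def make_bins(
    genome: ReferenceGenome,
    mappability: dict[str, np.ndarray],
    n_bins: int,
) -> list[GenomicBin]:
    """Partition the genome into bins of equal uniquely-mappable content.

    A genome-order sweep accumulates mappable positions and closes a bin at
    ``ceil(total_mappable / n_bins)`` of them; bins never cross chromosome
    boundaries.  The last bin of each chromosome absorbs the remainder and
    is pre-masked when its mappable count deviates more than 10% from the
    target.  GC is computed over each bin's full physical span.
    """
    total = sum(int(m.sum()) for m in mappability.values())
    if total < n_bins:
        raise ParameterError("fewer mappable positions than bins")
    if n_bins < len(genome.chrom_names):
        raise ParameterError("n_bins must be >= number of chromosomes")
    target = -(-total // n_bins)  # ceil

    bins: list[GenomicBin] = []
    for chrom, seq in zip(genome.chrom_names, genome.sequences):
        mp = np.flatnonzero(mappability[chrom])
        L = len(seq)
        if len(mp) == 0:
            bins.append(GenomicBin(chrom, 0, L, 0, _gc_frac(seq, 0, L), masked=True))
            continue
        cut_idx = np.arange(target, len(mp), target)
        bounds = [0] + [int(mp[i]) for i in cut_idx] + [L]
        counts = [target] * len(cut_idx) + [len(mp) - target * len(cut_idx)]
        for (s, e), c in zip(zip(bounds[:-1], bounds[1:]), counts):
            masked = abs(c - target) > 0.1 * target
            bins.append(GenomicBin(chrom, s, e, int(c), _gc_frac(seq, s, e),
                                   masked=masked))
    return bins


def _gc_frac(seq: str, s: int, e: int) -> float:
    sub = seq[s:e]
    gc = sub.count("G") + sub.count("C")
    acgt = gc + sub.count("A") + sub.count("T")
    return gc / acgt if acgt else float("nan")


def count_fragments(
    bins: list[GenomicBin], fragments: list[FragmentAlignment]
) -> list[GenomicBin]:
    """Fill ``raw_count``: uniquely mapped fragments by reference midpoint.

    Only fragments with ``is_unique`` are counted.  A midpoint on a bin
    boundary belongs to the bin whose half-open interval contains it.
    Masked bins are still counted (masking is applied downstream).
    """
    starts_by_chrom: dict[str, np.ndarray] = {}
    index_by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        index_by_chrom.setdefault(b.chrom, []).append(i)
    for chrom, idx in index_by_chrom.items():
        starts_by_chrom[chrom] = np.array([bins[i].start for i in idx])
    for b in bins:
        b.raw_count = 0
    for f in fragments:
        if not f.is_unique:
            continue
        if f.chrom not in starts_by_chrom:
            raise ParameterError(f"fragment on unknown chromosome {f.chrom}")
        mid = (f.ref_start + f.ref_end) // 2
        idx_list = index_by_chrom[f.chrom]
        last = bins[idx_list[-1]]
        if mid < 0 or mid >= last.end:
            raise ParameterError(f"fragment midpoint {mid} outside {f.chrom}")
        j = int(np.searchsorted(starts_by_chrom[f.chrom], mid, side="right")) - 1
        bins[idx_list[j]].raw_count += 1
    return bins


def mask_bad_bins(
    bins: list[GenomicBin], z_cutoff: float = 5.0, min_fold: float = 3.0
) -> list[GenomicBin]:
    """Iteratively mask bins with spuriously high counts.

    A bin is masked when its raw count exceeds ``median + z_cutoff * MAD``
    (MAD scaled by 1.4826 so ``z_cutoff`` reads as a robust z-score) *and*
    exceeds ``min_fold * median``; cutoffs are recomputed over surviving
    bins until a fixpoint.  The fold floor keeps genuine amplifications
    (which sit well above a tight count distribution in robust-z terms but
    only a factor ~2 above the median) out of the artifact mask; counts at
    centromere/telomere-like pileups are typically an order of magnitude
    above the bulk.  Amplifications beyond ``min_fold`` times the median
    cannot be distinguished from artifacts by this sample-only rule and
    would need a reference sample.  Iteration stops if the MAD degenerates
    to zero.
    """
    if len(bins) < 30:
        raise ParameterError("need at least 30 bins to mask outliers")
    while True:
        counts = np.array([b.raw_count for b in bins if not b.masked], dtype=float)
        if counts.size == 0:
            raise ParameterError("all bins masked")
        med = np.median(counts)
        mad = 1.4826 * np.median(np.abs(counts - med))
        if mad == 0:
            break
        cut = max(med + z_cutoff * mad, min_fold * med)
        changed = False
        for b in bins:
            if not b.masked and b.raw_count > cut:
                b.masked = True
                changed = True
        if not changed:
            break
    if all(b.masked for b in bins):
        raise ParameterError("all bins masked")
    return bins


def gc_correct(
    bins: list[GenomicBin], lowess_span: float = 0.3, robust_iter: int = 3
) -> list[GenomicBin]:
    """LOWESS GC-bias correction of raw counts.

    Fits count ~ GC over unmasked bins with locally weighted linear
    regression (tricube weights, ``lowess_span`` of the data per local fit,
    ``robust_iter`` robustness iterations) and sets
    ``corrected = raw - fitted + grand_mean``, floored at 0.  Masked bins get
    their raw count passed through.  Constant GC makes the correction the
    identity (with a warning).
    """
    unmasked = [b for b in bins if not b.masked]
    if len(unmasked) < 50:
        raise ParameterError("need at least 50 unmasked bins for GC correction")
    gc = np.array([b.gc for b in unmasked])
    counts = np.array([b.raw_count for b in unmasked], dtype=float)
    for b in bins:
        b.corrected_count = float(b.raw_count)
    if np.ptp(gc[np.isfinite(gc)]) < 1e-9:
        warnings.warn("constant GC across bins: GC correction is the identity")
        return bins
    fitted = _sm_lowess(
        counts, gc, frac=lowess_span, it=robust_iter, return_sorted=False,
        missing="drop",
    )
    corrected = np.maximum(counts - fitted + counts.mean(), 0.0)
    for b, c in zip(unmasked, corrected):
        b.corrected_count = float(c)
    return bins


def compute_ratios(bins: list[GenomicBin]) -> list[GenomicBin]:
    """ratio = corrected count / mean corrected count over unmasked bins."""
    unmasked = [b for b in bins if not b.masked]
    mean = float(np.mean([b.corrected_count for b in unmasked]))
    if mean <= 0:
        raise ParameterError("mean corrected count is zero")
    for b in bins:
        b.ratio = b.corrected_count / mean
    return bins


# ---------------------------------------------------------------- CBS ----

@njit(cache=True)
def _max_arc_t(x):
    """Max |t| over all arcs [i, j) of the circularized sequence, using the
    two-sample pooled-variance t statistic between arc and complement.
    Returns (t_max, i, j); (0, 0, n) when no valid arc exists."""
    n = len(x)
    s = np.zeros(n + 1)
    s2 = np.zeros(n + 1)
    for i in range(n):
        s[i + 1] = s[i] + x[i]
        s2[i + 1] = s2[i] + x[i] * x[i]
    tot = s[n]
    tot2 = s2[n]
    best = 0.0
    bi = 0
    bj = n
    for i in range(n):
        for j in range(i + 1, n + 1):
            n1 = j - i
            n2 = n - n1
            if n2 == 0:
                continue
            sum1 = s[j] - s[i]
            sum2 = tot - sum1
            m1 = sum1 / n1
            m2 = sum2 / n2
            ss1 = (s2[j] - s2[i]) - sum1 * m1
            ss2 = (tot2 - (s2[j] - s2[i])) - sum2 * m2
            if n <= 2:
                continue
            var = (ss1 + ss2) / (n - 2)
            if var <= 1e-300:
                var = 1e-300
            t = abs(m1 - m2) / np.sqrt(var * (1.0 / n1 + 1.0 / n2))
            if t > best:
                best = t
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _perm_exceed(perms, t_obs):
    """Number of permuted sequences whose max-arc |t| reaches t_obs."""
    count = 0
    for p in range(perms.shape[0]):
        t, _, _ = _max_arc_t(perms[p])
        if t >= t_obs:
            count += 1
    return count


def _split_segment(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Best significant arc (i, j) of x, or None.

    Permutation p-value = (1 + #{perm >= obs}) / (1 + n_perm); permutations
    stop early once significance is impossible."""
    n = len(x)
    if n < 2:
        return None
    t_obs, i, j = _max_arc_t(x)
    if t_obs == 0.0:
        return None
    limit = alpha * (1 + n_perm) - 1  # exceed > limit => p >= alpha
    exceed = 0
    done = 0
    batch = 100
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.empty((b, n))
        for r in range(b):
            perms[r] = rng.permutation(x)
        exceed += int(_perm_exceed(perms, t_obs))
        done += b
        if exceed > limit:
            return None
    p = (1 + exceed) / (1 + n_perm)
    if p < alpha:
        return i, j
    return None


def segment_cbs(
    ratios: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """Circular binary segmentation of one ordered ratio sequence.

    Recursively finds the arc maximizing the circular two-sample t statistic
    against its complement, accepts the split when the permutation p-value is
    below ``alpha``, and splits into up to three child segments.  Segments
    are returned in order with their mean ratios; deterministic given
    ``seed``.  Fewer than 2 bins yield a single trivial segment.
    """
    x = np.asarray(ratios, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        res = _split_segment(x[lo:hi], alpha, n_perm, rng)
        if res is None:
            return
        i, j = res
        cuts = sorted({lo + i, lo + j})
        pieces = [lo] + [c for c in cuts if lo < c < hi] + [hi]
        if len(pieces) == 2:
            return
        boundaries.extend(pieces[1:-1])
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    if len(x) >= 2:
        recurse(0, len(x))
    bounds = [0] + sorted(set(boundaries)) + [len(x)]
    return [
        Segment(a, b - 1, float(x[a:b].mean()))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def remove_spurious_segments(
    segments: list[Segment],
    ratios: np.ndarray,
    min_bins: int = 5,
    min_delta: float = 0.1,
) -> list[Segment]:
    """Merge spurious segments until a fixpoint.

    A segment is merged into the neighbor with the closer mean when it spans
    fewer than ``min_bins`` bins or differs from a neighbor's mean by less
    than ``min_delta``; means are recomputed after every merge.
    """
    x = np.asarray(ratios, dtype=float)
    segs = [Segment(s.first_bin, s.last_bin, s.mean_ratio) for s in segments]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k, seg in enumerate(segs):
            neighbors = []
            if k > 0:
                neighbors.append(k - 1)
            if k < len(segs) - 1:
                neighbors.append(k + 1)
            if not neighbors:
                continue
            deltas = [abs(seg.mean_ratio - segs[j].mean_ratio) for j in neighbors]
            if seg.n_bins < min_bins or min(deltas) < min_delta:
                j = neighbors[int(np.argmin(deltas))]
                a, b = sorted((k, j))
                merged = Segment(
                    segs[a].first_bin,
                    segs[b].last_bin,
                    float(x[segs[a].first_bin : segs[b].last_bin + 1].mean()),
                )
                segs[a : b + 1] = [merged]
                changed = True
                break
    return segs


def call_events(
    segments: list[Segment],
    n_bins: int,
    amp_cutoff: float = AMP_CUTOFF,
    del_cutoff: float = DEL_CUTOFF,
) -> list[str]:
    """Per-bin event state from segment means (boundary inclusive).

    amplified when the bin's segment mean >= ``amp_cutoff``; deleted when
    <= ``del_cutoff``; neutral otherwise.
    """
    if not amp_cutoff > del_cutoff > 0:
        raise ParameterError("need amp_cutoff > del_cutoff > 0")
    states = [None] * n_bins
    for seg in segments:
        if seg.mean_ratio >= amp_cutoff:
            s = STATE_AMPLIFIED
        elif seg.mean_ratio <= del_cutoff:
            s = STATE_DELETED
        else:
            s = STATE_NEUTRAL
        for k in range(seg.first_bin, seg.last_bin + 1):
            states[k] = s
    if any(s is None for s in states):
        raise ParameterError("bins not covered by any segment")
    return states


def profile(
    genome: ReferenceGenome,
    fragments: list[FragmentAlignment],
    n_bins: int,
    mappability: dict[str, np.ndarray] | None = None,
    probe_len: int = 40,
    z_cutoff: float = 5.0,
    mask_min_fold: float = 3.0,
    lowess_span: float = 0.3,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_seg_bins: int = 5,
    min_seg_delta: float = 0.1,
    amp_cutoff: float = AMP_CUTOFF,
    del_cutoff: float = DEL_CUTOFF,
    seed: int = 0,
    bins: list[GenomicBin] | None = None,
) -> CnvProfile:
    """Full pipeline: bins -> count -> mask -> GC-correct -> ratio -> CBS ->
    spurious-segment removal -> event calls.

    Pass ``bins`` to reuse a precomputed bin definition (required when two
    profiles must share a bin universe for comparison); otherwise bins are
    derived from ``mappability`` (computed here if not supplied).
    Segmentation runs per chromosome; segment indices refer to the genome-
    ordered unmasked-bin sequence.  Deterministic given ``seed``.
    """
    if bins is None:
        if mappability is None:
            mappability = compute_mappability(genome, probe_len)
        bins = make_bins(genome, mappability, n_bins)
    else:
        bins = [
            GenomicBin(b.chrom, b.start, b.end, b.n_mappable, b.gc, masked=b.masked)
            for b in bins
        ]
    count_fragments(bins, fragments)
    mask_bad_bins(bins, z_cutoff, mask_min_fold)
    gc_correct(bins, lowess_span)
    compute_ratios(bins)

    unmasked_index = np.array([i for i, b in enumerate(bins) if not b.masked])
    ratios = np.array([bins[i].ratio for i in unmasked_index])
    chroms = np.array([bins[i].chrom for i in unmasked_index])

    segments: list[Segment] = []
    offset = 0
    rng = np.random.default_rng(seed)
    for chrom in dict.fromkeys(chroms):  # preserves genome order
        sel = chroms == chrom
        x = ratios[sel]
        segs = segment_cbs(
            x, alpha=alpha, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        segs = remove_spurious_segments(segs, x, min_seg_bins, min_seg_delta)
        for s in segs:
            segments.append(
                Segment(s.first_bin + offset, s.last_bin + offset, s.mean_ratio)
            )
        offset += int(sel.sum())

    events = call_events(segments, len(ratios), amp_cutoff, del_cutoff)
    params = dict(
        n_bins=n_bins, probe_len=probe_len, z_cutoff=z_cutoff,
        mask_min_fold=mask_min_fold,
        lowess_span=lowess_span, alpha=alpha, n_perm=n_perm,
        min_seg_bins=min_seg_bins, min_seg_delta=min_seg_delta,
        amp_cutoff=amp_cutoff, del_cutoff=del_cutoff, seed=seed,
        n_fragments=len(fragments),
        n_unique_fragments=sum(1 for f in fragments if f.is_unique),
    )
    return CnvProfile(bins, segments, events, unmasked_index, params)
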