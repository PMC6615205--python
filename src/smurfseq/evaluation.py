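"""Precision/recall evaluation of fragment mapping against simulation truth.

Two views of accuracy: *fragment-level* (did the mapper identify each
embedded molecule, for counting purposes) and *base-level* (did it identify
the right reference bases).  A predicted fragment matches a truth fragment
when it is on the same read, chromosome and strand and the reciprocal
reference-interval overlap reaches ``min_overlap`` (default 0.5, the usual
structural-variant convention); matching is one-to-one, greedy by overlap.
Base-level metrics compare the multisets of (chromosome, position) reference
bases covered by predicted versus truth fragments, per read, then pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .align import FragmentAlignment
from .simulate import FragmentTruth

__all__ = ["EvalReport", "TruthFragment", "match_fragments", "evaluate"]


@dataclass(frozen=True)
class TruthFragment:
    """Truth record keyed by read id (flat form of per-read FragmentTruth)."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class EvalReport:
    fragment_precision: float
    fragment_recall: float
    base_precision: float
    base_recall: float
    n_truth: int
    n_predicted: int
    n_matched: int
    no_predictions: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def flatten_truth(reads) -> list[TruthFragment]:
    """Per-read FragmentTruth lists -> flat truth records."""
    out = []
    for r in reads:
        for f in r.fragments:
            out.append(TruthFragment(r.read_id, f.source_chrom, f.source_start,
                                     f.source_end, f.strand))
    return out


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def match_fragments(
    truth: list[TruthFragment],
    predicted: list[FragmentAlignment],
    min_overlap: float = 0.5,
) -> list[tuple[int, int, float]]:
    """One-to-one truth/prediction matching.

    Returns ``(truth_index, predicted_index, overlap)`` triples.  Candidate
    pairs require same read, chromosome and strand and reciprocal overlap
    >= ``min_overlap``; pairs are consumed greedily by descending overlap,
    ties by smaller reference start.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    by_key: dict[tuple, list[int]] = {}
    for ti, t in enumerate(truth):
        by_key.setdefault((t.read_id, t.chrom, t.strand), []).append(ti)
    cands: list[tuple[float, int, int, int]] = []
    for pi, p in enumerate(predicted):
        for ti in by_key.get((p.read_id, p.chrom, p.strand), []):
            t = truth[ti]
            ov = _reciprocal_overlap(t.ref_start, t.ref_end, p.ref_start, p.ref_end)
            if ov >= min_overlap:
                cands.append((ov, min(t.ref_start, p.ref_start), ti, pi))
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for ov, _, ti, pi in cands:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi, ov))
    return matches


def _positions(frags, chrom_index: dict[str, int]) -> np.ndarray:
    """Multiset of covered (chrom, position) values, encoded as a sorted
    int64 array (chrom index in the high bits)."""
    parts = []
    for f in frags:
        chrom = f.chrom if hasattr(f, "chrom") else f.source_chrom
        s = f.ref_start if hasattr(f, "ref_start") else f.source_start
        e = f.ref_end if hasattr(f, "ref_end") else f.source_end
        ci = np.int64(chrom_index[chrom])
        parts.append(np.arange(s, e, dtype=np.int64) | (ci << 40))
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(parts))


def _multiset_intersection(a: np.ndarray, b: np.ndarray) -> int:
    """Size of the multiset intersection of two sorted arrays."""
    av, ac = np.unique(a, return_counts=True)
    bv, bc = np.unique(b, return_counts=True)
    common, ia, ib = np.intersect1d(av, bv, return_indices=True)
    return int(np.minimum(ac[ia], bc[ib]).sum())


def evaluate(
    truth: list[TruthFragment],
    predicted: list[FragmentAlignment],
    min_overlap: float = 0.5,
    unique_only: bool = False,
) -> EvalReport:
    """Fragment- and base-level precision/recall of predictions vs truth.

    With no predictions, precision is reported as 1.0 with a warning flag
    (``no_predictions``) and recall as 0; the convention avoids a 0/0 while
    keeping the failure visible.  ``unique_only`` restricts predictions to
    uniquely-mapping fragments, matching the CNV pipeline's counting view.
    """
    if unique_only:
        predicted = [p for p in predicted if p.is_unique]
    matches = match_fragments(truth, predicted, min_overlap)
    n_t, n_p, n_m = len(truth), len(predicted), len(matches)

    read_ids = {t.read_id for t in truth} | {p.read_id for p in predicted}
    chroms = sorted({t.chrom for t in truth} | {p.chrom for p in predicted})
    chrom_index = {c: i for i, c in enumerate(chroms)}
    t_by_read: dict[str, list] = {r: [] for r in read_ids}
    p_by_read: dict[str, list] = {r: [] for r in read_ids}
    for t in truth:
        t_by_read[t.read_id].append(t)
    for p in predicted:
        p_by_read[p.read_id].append(p)
    matched_bases = truth_bases = pred_bases = 0
    for r in read_ids:
        ta = _positions(t_by_read[r], chrom_index)
        pa = _positions(p_by_read[r], chrom_index)
        truth_bases += len(ta)
        pred_bases += len(pa)
        if len(ta) and len(pa):
            matched_bases += _multiset_intersection(ta, pa)

    no_pred = n_p == 0
    if no_pred:
        warnings.warn("no predicted fragments: precision reported as 1.0")
    return EvalReport(
        fragment_precision=1.0 if no_pred else n_m / n_p,
        fragment_recall=0.0 if n_t == 0 else n_m / n_t,
        base_precision=1.0 if pred_bases == 0 else matched_bases / pred_bases,
        base_recall=0.0 if truth_bases == 0 else matched_bases / truth_bases,
        n_truth=n_t,
        n_predicted=n_p,
        n_matched=n_m,
        no_predictions=no_pred,
    )
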