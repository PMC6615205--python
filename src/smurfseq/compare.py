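"""Comparison of two CNV profiles sharing a bin universe.

Supports the standard concordance readouts: Pearson correlation of paired
bin ratios (bins masked in either profile excluded pairwise), event-level
precision/recall against a reference call set with a full 3x3 confusion
table, and read-granularity downsampling for depth-titration experiments.

Event matching requires *state* agreement (an amplification only matches an
amplification); ``ignore_direction=True`` relaxes this to mere
non-neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import FragmentAlignment
from .cnv import STATE_AMPLIFIED, STATE_DELETED, STATE_NEUTRAL, CnvProfile
from .genome import ParameterError

__all__ = ["ComparisonReport", "correlate", "compare_events", "downsample"]

_STATES = [STATE_AMPLIFIED, STATE_NEUTRAL, STATE_DELETED]


@dataclass
class ComparisonReport:
    pearson_r: float
    event_precision: float
    event_recall: float
    n_events_ref: int
    n_events_test: int
    confusion: pd.DataFrame  # rows = reference state, columns = test state

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["confusion"] = self.confusion.to_dict()
        return d


def _paired_states(ref: CnvProfile, test: CnvProfile) -> pd.DataFrame:
    for a, b in zip(ref.bins, test.bins):
        if (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end):
            raise ParameterError("profiles do not share a bin definition")
    ref_state = dict(zip(ref.unmasked_index.tolist(), ref.events))
    test_state = dict(zip(test.unmasked_index.tolist(), test.events))
    shared = sorted(set(ref_state) & set(test_state))
    return pd.DataFrame(
        dict(
            bin=shared,
            ref_ratio=[ref.bins[i].ratio for i in shared],
            test_ratio=[test.bins[i].ratio for i in shared],
            ref_state=[ref_state[i] for i in shared],
            test_state=[test_state[i] for i in shared],
        )
    )


def correlate(ref: CnvProfile, test: CnvProfile) -> tuple[float, pd.DataFrame]:
    """Pearson r over bins unmasked in both profiles, plus the paired table."""
    paired = _paired_states(ref, test)
    if len(paired) < 10:
        raise ParameterError("fewer than 10 shared unmasked bins")
    r = float(stats.pearsonr(paired.ref_ratio, paired.test_ratio).statistic)
    return r, paired


def compare_events(
    ref: CnvProfile, test: CnvProfile, ignore_direction: bool = False
) -> ComparisonReport:
    """Event-level precision/recall of test calls against reference calls.

    An event is a non-neutral bin state.  A test event is a true positive
    iff the reference bin carries the same non-neutral state (or any
    non-neutral state with ``ignore_direction``); a directional mismatch
    counts both as a false positive and as a missed reference event.
    """
    paired = _paired_states(ref, test)
    ref_s = paired.ref_state
    test_s = paired.test_state
    confusion = pd.crosstab(ref_s, test_s).reindex(
        index=_STATES, columns=_STATES, fill_value=0
    )
    confusion.index.name = "reference"
    confusion.columns.name = "test"
    ref_ev = ref_s != STATE_NEUTRAL
    test_ev = test_s != STATE_NEUTRAL
    if ignore_direction:
        tp = int((ref_ev & test_ev).sum())
    else:
        tp = int((ref_ev & (ref_s == test_s)).sum())
    n_ref, n_test = int(ref_ev.sum()), int(test_ev.sum())
    r, _ = correlate(ref, test)
    return ComparisonReport(
        pearson_r=r,
        event_precision=tp / n_test if n_test else 1.0,
        event_recall=tp / n_ref if n_ref else 1.0,
        n_events_ref=n_ref,
        n_events_test=n_test,
        confusion=confusion,
    )


def downsample(
    fragments: list[FragmentAlignment],
    n_reads: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
    by_read: bool = True,
) -> list[FragmentAlignment]:
    """Uniform subsampling without replacement, at read granularity.

    Sampling whole reads (the default) preserves the read-level structure of
    concatenated-fragment data; ``by_read=False`` samples fragments
    directly.  Exactly one of ``n_reads`` / ``fraction`` must be given.
    Deterministic given ``seed``.
    """
    if (n_reads is None) == (fraction is None):
        raise ParameterError("give exactly one of n_reads or fraction")
    rng = np.random.default_rng(seed)
    if by_read:
        read_ids = sorted({f.read_id for f in fragments})
        n = n_reads if n_reads is not None else int(round(fraction * len(read_ids)))
        if n > len(read_ids):
            raise ParameterError(f"cannot sample {n} of {len(read_ids)} reads")
        chosen = set(rng.choice(len(read_ids), size=n, replace=False).tolist())
        keep = {read_ids[i] for i in chosen}
        return [f for f in fragments if f.read_id in keep]
    n = n_reads if n_reads is not None else int(round(fraction * len(fragments)))
    if n > len(fragments):
        raise ParameterError(f"cannot sample {n} of {len(fragments)} fragments")
    idx = sorted(rng.choice(len(fragments), size=n, replace=False).tolist())
    return [fragments[i] for i in idx]
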