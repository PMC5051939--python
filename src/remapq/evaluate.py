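"""Mapping precision / sensitivity / FDR evaluation against simulated truth.

A mapping is *correct* when it lands on the true reference and strand and
both aligned boundaries are within 20% of the true locus, relative to the
alignment length.  Sweeping a mapQ cutoff partitions the simulated reads
into TP (kept and correct), FP (kept and wrong) and FN (filtered out,
unmapped, or missing), from which precision = TP/(TP+FP),
sensitivity = TP/(TP+FN) and FDR = 1 - precision follow.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .simulate import SimTruth

DEFAULT_CUTOFFS = (0, 3, 6, 10, 13, 20, 30, 40, 50, 60)


def is_correct(reference_name: str, start: int, end: int, strand: str,
               truth: SimTruth, align_length: int) -> bool:
    """Boundary rule: correct iff same reference and strand and both ends
    within ``0.2 * align_length`` of the true interval."""
    if reference_name != truth.reference_name or strand != truth.strand:
        return False
    tol = 0.2 * align_length
    return (abs(start - truth.start) <= tol
            and abs(end - truth.end) <= tol)


def record_is_correct(rec: pysam.AlignedSegment,
                      truth: Optional[SimTruth] = None) -> bool:
    """Apply the boundary rule to a mapped SAM record whose name encodes
    its truth."""
    if rec.is_unmapped:
        return False
    if truth is None:
        truth = SimTruth.decode(rec.query_name)
    length = rec.query_alignment_length or (rec.query_length or 1)
    return is_correct(rec.reference_name, rec.reference_start,
                      rec.reference_end, "-" if rec.is_reverse else "+",
                      truth, length)


def sweep_mapq(primaries: Iterable[pysam.AlignedSegment],
               cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
               total: Optional[int] = None) -> pd.DataFrame:
    """Evaluate primary alignments at a series of mapQ cutoffs.

    ``primaries`` holds at most one record per simulated read (unmapped
    records allowed).  Reads below a cutoff, unmapped, or absent entirely
    (when ``total`` exceeds the records seen) count as FN.  Returns a
    DataFrame with columns cutoff/TP/FP/FN/precision/sensitivity/FDR.
    """
    mapqs: list[int] = []
    correct: list[bool] = []
    n_seen = 0
    for rec in primaries:
        n_seen += 1
        if rec.is_unmapped:
            continue
        mapqs.append(rec.mapping_quality)
        correct.append(record_is_correct(rec))
    if total is None:
        total = n_seen
    elif total < n_seen:
        raise ValueError("total is smaller than the number of records seen")
    mq = np.asarray(mapqs)
    ok = np.asarray(correct, dtype=bool)

    rows = []
    for cut in cutoffs:
        kept = mq >= cut
        tp = int(np.sum(kept & ok))
        fp = int(np.sum(kept & ~ok))
        fn = total - tp - fp
        precision = tp / (tp + fp) if tp + fp else float("nan")
        sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        rows.append({"cutoff": cut, "TP": tp, "FP": fp, "FN": fn,
                     "precision": precision, "sensitivity": sensitivity,
                     "FDR": 1.0 - precision})
    return pd.DataFrame(rows)


def random_baseline(groups: Iterable[Sequence[pysam.AlignedSegment]],
                    rng: np.random.Generator) -> list[pysam.AlignedSegment]:
    """Pick one candidate uniformly at random from each read's candidate
    list — the no-model baseline the posterior selection is compared to."""
    picks = []
    for records in groups:
        records = list(records)
        picks.append(records[int(rng.integers(0, len(records)))])
    return picks
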