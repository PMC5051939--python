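"""Maximum-scoring insert range and CIGAR/MD-consistent trimming.

Reads can carry non-genomic sequence (untrimmed adapters, barcodes, RNA
modifications, chimeric joins) that aligners without local-alignment support
force into the alignment.  The true insert is re-estimated as the contiguous
range of expanded alignment positions maximising a per-position score
(match reward, mismatch/gap/clip penalties), found by a linear dynamic
program with the recurrence ``S(i) = max(S(i-1) + A_i, 0)``.  Positions
outside the best range are soft-clipped and the record's CIGAR, MD tag and
start coordinate are rewritten so the trimmed record remains valid SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AlignmentStatus,
    CandidateAlignment,
    PenaltyConfig,
)

_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT, _CHARD, _CPAD, _CEQUAL, _CDIFF = range(9)

_READ_OPS = (_CMATCH, _CINS, _CSOFT, _CEQUAL, _CDIFF)
_REF_OPS = (_CMATCH, _CDEL, _CREF_SKIP, _CEQUAL, _CDIFF)


@dataclass
class ScoreConfig:
    """Per-position scores for the insert-range dynamic program.

    ``match_score``/``mismatch_score`` reward/penalise aligned bases; gap
    and clip positions are penalised by the same gammas used for the
    likelihood model (as subtractive penalties).
    """

    match_score: float = 1.0
    mismatch_score: float = -2.0
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")


@dataclass(frozen=True)
class InsertRange:
    """Half-open index range into the expanded position vector, with its
    score.  The empty range has score 0."""

    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError("invalid range")
        if self.score < 0:
            raise ValueError("range score is never negative")

    def __len__(self) -> int:
        return self.end - self.start


def position_scores(candidate: CandidateAlignment,
                    config: ScoreConfig) -> np.ndarray:
    """Per-position insert scores A_i from the candidate's statuses."""
    g = config.penalties
    table = np.array([
        config.match_score,      # MATCH
        config.mismatch_score,   # MISMATCH
        -g.gamma_open,           # GAP_OPEN
        -g.gamma_ext,            # GAP_EXT
        -g.gamma_soft,           # SOFT_CLIP
        -g.gamma_hard,           # HARD_CLIP
        0.0,                     # IGNORED
    ])
    return table[candidate.statuses]


def best_insert_range(scores: Sequence[float]) -> InsertRange:
    """Maximum-scoring contiguous range of ``scores``.

    Linear scan with the recurrence ``S(i) = max(S(i-1) + A_i, 0)`` plus
    traceback of the running start.  Ties are broken leftmost first, then
    longest.  If no range has positive score the empty range (score 0) is
    returned.
    """
    best_score = 0.0
    best_start = best_end = 0
    cur = 0.0
    cur_start = 0
    for i, a in enumerate(np.asarray(scores, dtype=np.float64)):
        cur += a
        if cur < 0.0:
            cur = 0.0
            cur_start = i + 1
            continue
        if cur > best_score or (
                cur == best_score and best_score > 0.0 and
                (cur_start < best_start or
                 (cur_start == best_start and i + 1 > best_end))):
            best_score = cur
            best_start = cur_start
            best_end = i + 1
    if best_score <= 0.0:
        return InsertRange(0, 0, 0.0)
    return InsertRange(best_start, best_end, float(best_score))


def _snap_range(candidate: CandidateAlignment, rng: InsertRange) -> tuple[int, int]:
    """Snap a range to op-run boundaries so the trimmed record stays valid.

    A range edge inside a deletion run is pulled back to the run boundary
    (a deletion cannot be half-kept), and edges are shrunk over leading or
    trailing D/N/P so the kept alignment starts and ends on a read base.
    """
    ops = candidate.ops
    n = len(ops)
    s, e = rng.start, rng.end
    # exclude a partially-covered deletion at the left edge
    if s < e and s > 0 and ops[s] == _CDEL and ops[s - 1] == _CDEL:
        while s < e and ops[s] == _CDEL:
            s += 1
    # ... and at the right edge
    if e > s and e < n and ops[e - 1] == _CDEL and ops[e] == _CDEL:
        while e > s and ops[e - 1] == _CDEL:
            e -= 1
    # kept alignment must not start/end with D/N/P
    while s < e and ops[s] in (_CDEL, _CREF_SKIP, _CPAD):
        s += 1
    while e > s and ops[e - 1] in (_CDEL, _CREF_SKIP, _CPAD):
        e -= 1
    return s, e


def trim_to_insert(candidate: CandidateAlignment,
                   rng: InsertRange) -> CandidateAlignment:
    """Soft-clip everything outside ``rng`` and rewrite the record.

    Read bases outside the range become soft clips; reference-consuming
    positions outside the range are dropped and the start coordinate is
    advanced.  The attached SAM record (if any) gets a rewritten CIGAR, MD
    tag and position.  An empty range marks the record unmapped.  Trimming
    to the full range returns the candidate unchanged; the operation is
    idempotent.
    """
    n = len(candidate.ops)
    s, e = _snap_range(candidate, rng)

    if s >= e:
        if candidate.record is not None:
            candidate.record.is_unmapped = True
            candidate.record.cigarstring = None
            candidate.record.mapping_quality = 0
            if candidate.record.has_tag("MD"):
                candidate.record.set_tag("MD", None)
        candidate.mapq = 0
        candidate.posterior = None
        return candidate

    keep = np.zeros(n, dtype=bool)
    keep[s:e] = True
    # outside positions: read-consuming become soft clips, the rest vanish
    outside_read = ~keep & np.isin(candidate.ops, _READ_OPS)
    drop = ~keep & ~outside_read & (candidate.ops != _CHARD)

    if not drop.any() and not (
            outside_read & (candidate.ops != _CSOFT)).any():
        return candidate  # nothing changes (full-range or already trimmed)

    sel = ~drop
    ops = candidate.ops[sel].copy()
    statuses = candidate.statuses[sel].copy()
    qualities = candidate.qualities[sel].copy()
    read_bases = candidate.read_bases[sel].copy()
    ref_bases = candidate.ref_bases[sel].copy()
    ref_pos = candidate.ref_pos[sel].copy()
    read_pos = candidate.read_pos[sel].copy()

    clip = outside_read[sel]
    ops[clip] = _CSOFT
    statuses[clip] = AlignmentStatus.SOFT_CLIP
    ref_bases[clip] = ""
    ref_pos[clip] = -1

    # an insertion left touching the new clip region merges into it
    _merge_edge_insertions(ops, statuses, ref_bases, ref_pos)

    aligned = np.isin(ops, _REF_OPS) & (ref_pos >= 0)
    new_start = int(ref_pos[aligned].min())
    new_end = int(ref_pos[aligned].max()) + 1
    mm = int(np.sum(statuses == AlignmentStatus.MISMATCH))
    indels = sum(1 for op, _ in _runs(ops) if op in (_CINS, _CDEL))

    trimmed = CandidateAlignment(
        read_name=candidate.read_name,
        reference_name=candidate.reference_name,
        start=new_start,
        end=new_end,
        strand=candidate.strand,
        ops=ops,
        statuses=statuses,
        qualities=qualities,
        read_bases=read_bases,
        ref_bases=ref_bases,
        ref_pos=ref_pos,
        read_pos=read_pos,
        align_length=int(np.sum(statuses != AlignmentStatus.IGNORED)),
        mismatch_count=mm,
        indel_count=indels,
        clip_quality=candidate.clip_quality,
        record=candidate.record,
    )
    if trimmed.record is not None:
        rec = trimmed.record
        rec.reference_start = new_start
        rec.cigarstring = trimmed.cigarstring
        if rec.has_tag("MD"):
            rec.set_tag("MD", trimmed.md_tag() if trimmed.has_ref_bases
                        else None)
    return trimmed


def _merge_edge_insertions(ops, statuses, ref_bases, ref_pos) -> None:
    """Convert insertion positions adjacent to terminal clip regions into
    soft clips (an I op cannot border the read end in valid SAM)."""
    n = len(ops)
    i = 0
    while i < n and ops[i] in (_CHARD, _CSOFT, _CINS):
        if ops[i] == _CINS:
            ops[i] = _CSOFT
            statuses[i] = AlignmentStatus.SOFT_CLIP
            ref_bases[i] = ""
            ref_pos[i] = -1
        i += 1
    i = n - 1
    while i >= 0 and ops[i] in (_CHARD, _CSOFT, _CINS):
        if ops[i] == _CINS:
            ops[i] = _CSOFT
            statuses[i] = AlignmentStatus.SOFT_CLIP
            ref_bases[i] = ""
            ref_pos[i] = -1
        i -= 1


def _runs(values: np.ndarray):
    i, n = 0, len(values)
    while i < n:
        j = i + 1
        while j < n and values[j] == values[i]:
            j += 1
        yield int(values[i]), j - i
        i = j
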