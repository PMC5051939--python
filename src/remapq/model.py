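"""Per-position alignment representation.

A SAM record is expanded into parallel per-position vectors (one entry per
CIGAR-consumed position, including clips and ref-skips) describing the
alignment status, the base quality, and the read/reference bases involved.
Every downstream computation — alignment likelihood, posterior mapQ, and the
maximum-scoring insert-range dynamic program — consumes this representation.

Coordinates are 0-based half-open internally; SAM I/O converts to/from
1-based at the boundary (pysam already does this).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

# pysam CIGAR op codes
_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT, _CHARD, _CPAD, _CEQUAL, _CDIFF = range(9)

_OP_CHARS = "MIDNSHP=X"


class AlignmentStatus(enum.IntEnum):
    """Status of one expanded alignment position.

    Every expanded position has exactly one status.  ``IGNORED`` covers
    reference skips (``N``, introns) and padding (``P``), which contribute
    nothing to likelihoods or insert scores.
    """

    MATCH = 0
    MISMATCH = 1
    GAP_OPEN = 2
    GAP_EXT = 3
    SOFT_CLIP = 4
    HARD_CLIP = 5
    IGNORED = 6


@dataclass
class PenaltyConfig:
    """Penalty scores and scaling constants for alignment likelihoods.

    Each gamma is the relative chance of the corresponding alignment status
    compared to a mismatch, in log10 units; larger values penalise the status
    more heavily.  ``phred_scale`` is the phred scaling factor and is always
    -10.  ``effective_genome_size`` documents the locus-prior denominator; it
    cancels in the posterior normalisation and is never used numerically.
    """

    gamma_open: float = 2.0
    gamma_ext: float = 1.0
    gamma_soft: float = 1.0
    gamma_hard: float = 1.0
    gamma_snp: float = 1.0
    gamma_indel: float = 2.0
    gamma_mnp: float = 2.0
    phred_scale: float = -10.0
    mapq_cap: int = 250
    clip_window: int = 5
    effective_genome_size: float = 3.1e9

    def __post_init__(self) -> None:
        for name in ("gamma_open", "gamma_ext", "gamma_soft", "gamma_hard",
                     "gamma_snp", "gamma_indel", "gamma_mnp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.phred_scale != -10.0:
            raise ValueError("phred_scale is fixed at -10")
        if self.clip_window < 1:
            raise ValueError("clip_window must be positive")


@dataclass
class CandidateAlignment:
    """One candidate alignment of a read, expanded per position.

    The parallel vectors ``ops``, ``statuses``, ``qualities``, ``read_bases``
    and ``ref_bases`` all have one entry per expanded position (the sum of
    all CIGAR op lengths).  ``align_length`` counts the non-IGNORED positions
    and serves as the locus-prior weight.
    """

    read_name: str
    reference_name: str
    start: int
    end: int
    strand: str
    ops: np.ndarray
    statuses: np.ndarray
    qualities: np.ndarray
    read_bases: np.ndarray
    ref_bases: np.ndarray
    ref_pos: np.ndarray
    read_pos: np.ndarray
    align_length: int
    mismatch_count: int
    indel_count: int
    clip_quality: Optional[tuple[float, float]] = None
    log_lik: Optional[float] = None
    posterior: Optional[float] = None
    mapq: Optional[int] = None
    is_primary: bool = False
    record: Optional[pysam.AlignedSegment] = None

    def __post_init__(self) -> None:
        n = len(self.statuses)
        if not (len(self.qualities) == len(self.ops) == n):
            raise ValueError("statuses/qualities/ops must be index-aligned")
        if self.align_length < 1:
            raise ValueError("alignment must have at least one scored position")

    @property
    def cigarstring(self) -> str:
        """CIGAR string reconstructed from the expanded op vector."""
        parts = []
        for op, length in iter_runs(self.ops):
            parts.append(f"{length}{_OP_CHARS[op]}")
        return "".join(parts)

    @property
    def has_ref_bases(self) -> bool:
        """True when reference bases at mismatches/deletions are known
        (MD present on input), so an MD tag can be regenerated."""
        need = (self.statuses == AlignmentStatus.MISMATCH) | (
            (self.ops == _CDEL))
        return bool(np.all(self.ref_bases[need] != "") if need.any() else True)

    def md_tag(self) -> str:
        """Canonical MD:Z string regenerated from the expanded vectors."""
        if not self.has_ref_bases:
            raise ValueError("reference bases unknown; cannot build MD")
        out: list[str] = []
        run = 0
        i = 0
        n = len(self.ops)
        while i < n:
            op = self.ops[i]
            if op in (_CMATCH, _CEQUAL, _CDIFF):
                if self.statuses[i] == AlignmentStatus.MISMATCH:
                    out.append(str(run))
                    out.append(str(self.ref_bases[i]).upper())
                    run = 0
                else:
                    run += 1
                i += 1
            elif op == _CDEL:
                out.append(str(run))
                run = 0
                deleted = []
                while i < n and self.ops[i] == _CDEL:
                    deleted.append(str(self.ref_bases[i]).upper())
                    i += 1
                out.append("^" + "".join(deleted))
            else:  # I, S, H, P, N never appear in MD
                i += 1
        out.append(str(run))
        return "".join(out)

    def locus(self) -> tuple[str, int, int, str]:
        return (self.reference_name, self.start, self.end, self.strand)


@dataclass
class ReadGroup:
    """All candidate alignments of one read; the unit of posterior
    normalisation."""

    read_name: str
    candidates: list[CandidateAlignment]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("ReadGroup requires at least one candidate")
        for c in self.candidates:
            if c.read_name != self.read_name:
                raise ValueError("all candidates must share read_name")


def iter_runs(values: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (value, run_length) over consecutive runs of an int vector."""
    n = len(values)
    i = 0
    while i < n:
        j = i + 1
        while j < n and values[j] == values[i]:
            j += 1
        yield int(values[i]), j - i
        i = j


def collapse_duplicates(candidates: list[CandidateAlignment]) -> list[CandidateAlignment]:
    """Drop exact duplicate candidates (same refname, start, CIGAR, strand),
    keeping the first occurrence."""
    seen = set()
    out = []
    for c in candidates:
        key = (c.reference_name, c.start, c.cigarstring, c.strand)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


class AlignmentExpansionError(ValueError):
    """Raised when a SAM record cannot be expanded (missing MD with an
    ambiguous M CIGAR, or CIGAR/MD inconsistency)."""


def expand_alignment(record: pysam.AlignedSegment,
                     md_tag: Optional[str] = None) -> CandidateAlignment:
    """Expand a mapped SAM record into a :class:`CandidateAlignment`.

    Mismatches are resolved from the MD:Z tag, or directly from ``=``/``X``
    CIGAR operations when the record uses that dialect.  Records whose ``M``
    operations cannot be classified (no MD, no =/X) are rejected.

    Parameters
    ----------
    record:
        A mapped pysam record with CIGAR and base qualities.
    md_tag:
        Optional MD string overriding the record's own MD:Z tag.
    """
    if record.is_unmapped or record.cigartuples is None:
        raise AlignmentExpansionError(f"{record.query_name}: record is unmapped")
    quals = record.query_qualities
    seq = record.query_sequence
    if quals is None or seq is None:
        raise AlignmentExpansionError(
            f"{record.query_name}: record lacks sequence or base qualities")

    cig = record.cigartuples
    ops_present = {op for op, _ in cig}
    if md_tag is not None:
        record.set_tag("MD", md_tag)
    has_md = record.has_tag("MD")
    if _CMATCH in ops_present and not has_md:
        raise AlignmentExpansionError(
            f"{record.query_name}: CIGAR contains M but no MD tag and no =/X "
            "ops; match vs mismatch cannot be classified")

    # Reference bases (uppercase = match, lowercase = mismatch) keyed by
    # query position for aligned bases and by reference position for
    # deletions; derived from MD by pysam.
    ref_by_q: dict[int, str] = {}
    ref_by_r: dict[int, str] = {}
    if has_md:
        try:
            for q, r, b in record.get_aligned_pairs(with_seq=True):
                if b is None:
                    continue
                if q is not None:
                    ref_by_q[q] = b
                else:
                    ref_by_r[r] = b
        except (ValueError, AssertionError) as exc:
            raise AlignmentExpansionError(
                f"{record.query_name}: CIGAR/MD inconsistency: {exc}") from exc

    n = sum(length for _, length in cig)
    ops = np.empty(n, dtype=np.uint8)
    statuses = np.empty(n, dtype=np.uint8)
    qualities = np.zeros(n, dtype=np.float64)
    read_bases = np.full(n, "", dtype="U1")
    ref_bases = np.full(n, "", dtype="U1")
    ref_pos = np.full(n, -1, dtype=np.int64)
    read_pos = np.full(n, -1, dtype=np.int64)

    i = 0          # expanded index
    qpos = 0       # query cursor (soft clips consume query)
    rpos = record.reference_start
    mismatch_count = 0
    indel_count = 0
    for op, length in cig:
        if op in (_CMATCH, _CEQUAL, _CDIFF):
            for _ in range(length):
                ops[i] = op
                base = seq[qpos]
                read_bases[i] = base
                qualities[i] = quals[qpos]
                ref_pos[i] = rpos
                read_pos[i] = qpos
                if has_md:
                    rb = ref_by_q.get(qpos)
                    if rb is None or not rb.isalpha():
                        raise AlignmentExpansionError(
                            f"{record.query_name}: MD does not cover query "
                            f"position {qpos}")
                    ref_bases[i] = rb.upper()
                    mm = rb.islower()
                else:  # =/X dialect
                    mm = op == _CDIFF
                    if op == _CEQUAL:
                        ref_bases[i] = base
                if op == _CEQUAL and has_md and mm:
                    raise AlignmentExpansionError(
                        f"{record.query_name}: '=' op disagrees with MD")
                statuses[i] = (AlignmentStatus.MISMATCH if mm
                               else AlignmentStatus.MATCH)
                mismatch_count += int(mm)
                qpos += 1
                rpos += 1
                i += 1
        elif op == _CINS:
            indel_count += 1
            for k in range(length):
                ops[i] = op
                statuses[i] = (AlignmentStatus.GAP_OPEN if k == 0
                               else AlignmentStatus.GAP_EXT)
                read_bases[i] = seq[qpos]
                qualities[i] = quals[qpos]
                read_pos[i] = qpos
                qpos += 1
                i += 1
        elif op == _CDEL:
            indel_count += 1
            for k in range(length):
                ops[i] = op
                statuses[i] = (AlignmentStatus.GAP_OPEN if k == 0
                               else AlignmentStatus.GAP_EXT)
                if has_md:
                    rb = ref_by_r.get(rpos)
                    if rb is None or not rb.isalpha():
                        raise AlignmentExpansionError(
                            f"{record.query_name}: MD does not cover deleted "
                            f"reference position {rpos}")
                    ref_bases[i] = rb.upper()
                qualities[i] = np.nan  # synthesised below
                ref_pos[i] = rpos
                rpos += 1
                i += 1
        elif op in (_CREF_SKIP, _CPAD):
            for _ in range(length):
                ops[i] = op
                statuses[i] = AlignmentStatus.IGNORED
                if op == _CREF_SKIP:
                    ref_pos[i] = rpos
                    rpos += 1
                i += 1
        elif op == _CSOFT:
            for _ in range(length):
                ops[i] = op
                statuses[i] = AlignmentStatus.SOFT_CLIP
                read_bases[i] = seq[qpos]
                qualities[i] = quals[qpos]
                read_pos[i] = qpos
                qpos += 1
                i += 1
        elif op == _CHARD:
            for _ in range(length):
                ops[i] = op
                statuses[i] = AlignmentStatus.HARD_CLIP
                qualities[i] = np.nan  # filled by estimate_clip_quality
                i += 1
        else:
            raise AlignmentExpansionError(
                f"{record.query_name}: unsupported CIGAR op code {op}")

    _synthesise_deletion_qualities(ops, qualities)

    align_length = int(np.sum(statuses != AlignmentStatus.IGNORED))
    cand = CandidateAlignment(
        read_name=record.query_name,
        reference_name=record.reference_name,
        start=record.reference_start,
        end=rpos,
        strand="-" if record.is_reverse else "+",
        ops=ops,
        statuses=statuses,
        qualities=qualities,
        read_bases=read_bases,
        ref_bases=ref_bases,
        ref_pos=ref_pos,
        read_pos=read_pos,
        align_length=align_length,
        mismatch_count=mismatch_count,
        indel_count=indel_count,
        record=record,
    )
    return cand


def _synthesise_deletion_qualities(ops: np.ndarray, qualities: np.ndarray) -> None:
    """Deletion positions carry no read base; assign each deletion run the
    mean of the two flanking read-base qualities (one flank at alignment
    ends)."""
    has_read_qual = np.isin(ops, (_CMATCH, _CEQUAL, _CDIFF, _CINS, _CSOFT))
    read_idx = np.flatnonzero(has_read_qual)
    if len(read_idx) == 0:
        return
    n = len(ops)
    i = 0
    while i < n:
        if ops[i] == _CDEL:
            j = i
            while j < n and ops[j] == _CDEL:
                j += 1
            left = read_idx[read_idx < i]
            right = read_idx[read_idx >= j]
            flanks = []
            if len(left):
                flanks.append(qualities[left[-1]])
            if len(right):
                flanks.append(qualities[right[0]])
            qualities[i:j] = float(np.mean(flanks))
            i = j
        else:
            i += 1


def estimate_clip_quality(candidate: CandidateAlignment,
                          config: PenaltyConfig) -> float:
    """Estimate the base quality of hard-clipped (unobserved) bases.

    Each hard-clipped end is assigned the mean phred quality of up to
    ``config.clip_window`` observed bases immediately adjacent to that end.
    The per-end values are written into the candidate's quality vector at
    the hard-clip positions; the returned scalar is the mean over clipped
    ends (for reporting).  Falls back to the mean of all observed qualities
    if a window is empty.
    """
    hard = candidate.ops == _CHARD
    observed = np.isin(candidate.ops, (_CMATCH, _CEQUAL, _CDIFF, _CINS, _CSOFT))
    obs_quals = candidate.qualities[observed]
    if len(obs_quals) == 0:
        raise ValueError("candidate has no observed bases")
    fallback = float(np.mean(obs_quals))
    w = config.clip_window
    n = len(candidate.ops)

    left_val = right_val = None
    # leading hard-clip run
    if hard[0]:
        j = 0
        while j < n and hard[j]:
            j += 1
        window = candidate.qualities[observed][:w]
        left_val = float(np.mean(window)) if len(window) else fallback
        candidate.qualities[:j] = left_val
    # trailing hard-clip run
    if hard[-1]:
        j = n
        while j > 0 and hard[j - 1]:
            j -= 1
        window = candidate.qualities[observed][-w:]
        right_val = float(np.mean(window)) if len(window) else fallback
        candidate.qualities[j:] = right_val

    vals = [v for v in (left_val, right_val) if v is not None]
    if not vals:
        return fallback
    candidate.clip_quality = (
        left_val if left_val is not None else vals[0],
        right_val if right_val is not None else vals[0],
    )
    return float(np.mean(vals))
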