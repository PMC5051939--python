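"""Streaming SAM/BAM processing: grouping, scoring, filtering, writing.

Input must contain *all* candidate alignments per read (multi-mapping
enabled) and be name-grouped or name-sorted, so that one read's candidates
arrive contiguously and peak memory stays bounded by the largest group.
Output records carry the recomputed MAPQ plus diagnostic tags:

    XL:f  log10 alignment likelihood      XP:f  posterior probability
    XN:i  number of candidates            XM:i  mismatches
    XO:i  indels

These tag names are this package's convention.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pysam

from . import __version__
from .insert import ScoreConfig, best_insert_range, position_scores, trim_to_insert
from .likelihood import (
    KnownVariantIndex,
    log_likelihood,
    log_likelihood_variant_aware,
)
from .model import (
    AlignmentExpansionError,
    CandidateAlignment,
    PenaltyConfig,
    ReadGroup,
    collapse_duplicates,
    expand_alignment,
)
from .posterior import (
    CandidatePair,
    FragmentModel,
    PairGroup,
    estimate_fragment_model,
    mate_distance,
    orphan_to_pair,
    pe_posteriors,
    se_posteriors,
    select_best,
)

logger = logging.getLogger(__name__)


class SortOrderError(ValueError):
    """Input is not name-grouped (coordinate-sorted, or a read name
    reappears after its group was closed)."""


@dataclass
class RunConfig:
    """Everything a filtering run needs beyond the penalty/score tables."""

    mode: str = "SE"                      # SE | PE
    enable_1dp: bool = False
    variant_vcf: Optional[str] = None
    strict_literal_variants: bool = False
    min_mapq_out: int = 0
    max_report: int = 10                  # non-primary hits kept
    min_frag_n: int = 1000                # fragment-model reliability floor
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)
    scores: ScoreConfig = field(default_factory=ScoreConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("SE", "PE"):
            raise ValueError("mode must be SE or PE")
        if not 0 <= self.min_mapq_out <= self.penalties.mapq_cap:
            raise ValueError("min_mapq_out out of range")


def group_stream(af: pysam.AlignmentFile
                 ) -> Iterator[tuple[str, list[pysam.AlignedSegment]]]:
    """Yield (read_name, records) per read from a name-grouped file.

    Coordinate-sorted input and mid-file name-order violations raise
    :class:`SortOrderError` instead of silently mis-grouping.
    """
    so = af.header.to_dict().get("HD", {}).get("SO")
    if so == "coordinate":
        raise SortOrderError(
            "input is coordinate-sorted; name-sort it first "
            "(samtools sort -n)")
    current: Optional[str] = None
    bucket: list[pysam.AlignedSegment] = []
    closed: set[int] = set()  # hashes of finished names
    for rec in af:
        name = rec.query_name
        if name == current:
            bucket.append(rec)
            continue
        if current is not None:
            yield current, bucket
            closed.add(hash(current))
        if hash(name) in closed:
            raise SortOrderError(
                f"read name {name!r} reappears after its group was closed; "
                "input is not name-grouped")
        current = name
        bucket = [rec]
    if current is not None:
        yield current, bucket


def _expand_mapped(records: Sequence[pysam.AlignedSegment]
                   ) -> list[CandidateAlignment]:
    out = []
    for rec in records:
        if rec.is_unmapped:
            continue
        try:
            out.append(expand_alignment(rec))
        except AlignmentExpansionError as exc:
            logger.warning("rejecting record: %s", exc)
    return collapse_duplicates(out)


def _apply_1dp(cands: list[CandidateAlignment],
               scores: ScoreConfig) -> list[CandidateAlignment]:
    kept = []
    for c in cands:
        rng = best_insert_range(position_scores(c, scores))
        if len(rng) == 0:
            continue  # nothing alignable; candidate dropped
        kept.append(trim_to_insert(c, rng))
    return kept


def _score(cands: list[CandidateAlignment], cfg: RunConfig,
           variants: Optional[KnownVariantIndex]) -> None:
    for c in cands:
        if variants is not None:
            log_likelihood_variant_aware(
                c, variants, cfg.penalties,
                strict_literal=cfg.strict_literal_variants)
        else:
            log_likelihood(c, cfg.penalties)


def process_se_group(records: Sequence[pysam.AlignedSegment],
                     cfg: RunConfig,
                     variants: Optional[KnownVariantIndex] = None
                     ) -> Optional[list[CandidateAlignment]]:
    """Expand, optionally 1DP-trim, score and rank one read's candidates.
    Returns the posterior-ordered candidates, or None when nothing maps."""
    cands = _expand_mapped(records)
    if cfg.enable_1dp:
        cands = _apply_1dp(cands, cfg.scores)
    if not cands:
        return None
    _score(cands, cfg, variants)
    group = ReadGroup(read_name=records[0].query_name, candidates=cands)
    se_posteriors(group, cfg.penalties)
    return select_best(group, cfg.penalties)


def _match_pairs(first: list[CandidateAlignment],
                 second: list[CandidateAlignment]
                 ) -> tuple[list[tuple[CandidateAlignment, CandidateAlignment]],
                            list[CandidateAlignment]]:
    """Join mate candidates via their SAM mate pointers; return matched
    (mate1, mate2) tuples plus the unmatched leftovers."""
    pairs = []
    used1: set[int] = set()
    used2: set[int] = set()
    for i, c1 in enumerate(first):
        r1 = c1.record
        for j, c2 in enumerate(second):
            if j in used2:
                continue
            r2 = c2.record
            if (r1.next_reference_id == r2.reference_id
                    and r1.next_reference_start == r2.reference_start
                    and r2.next_reference_id == r1.reference_id
                    and r2.next_reference_start == r1.reference_start):
                pairs.append((c1, c2))
                used1.add(i)
                used2.add(j)
                break
    orphans = [c for i, c in enumerate(first) if i not in used1]
    orphans += [c for j, c in enumerate(second) if j not in used2]
    return pairs, orphans


def process_pe_group(records: Sequence[pysam.AlignedSegment],
                     cfg: RunConfig,
                     frag_model: FragmentModel,
                     variants: Optional[KnownVariantIndex] = None
                     ) -> Optional[list[CandidatePair]]:
    """Expand, pair, score and rank one fragment's candidate pairs.

    Candidates whose mate has no alignment at their locus are paired with a
    fully soft-clipped pseudo-mate (scored with the constant pairing
    density) and compete in the same posterior pool.
    """
    mate1 = _expand_mapped([r for r in records if r.is_read1])
    mate2 = _expand_mapped([r for r in records if r.is_read2 or not r.is_read1])
    if cfg.enable_1dp:
        mate1 = _apply_1dp(mate1, cfg.scores)
        mate2 = _apply_1dp(mate2, cfg.scores)
    if not mate1 and not mate2:
        return None
    _score(mate1 + mate2, cfg, variants)

    unmapped_quals = {}
    for r in records:
        if r.is_unmapped and r.query_qualities is not None:
            unmapped_quals[1 if r.is_read1 else 2] = list(r.query_qualities)

    matched, orphans = _match_pairs(mate1, mate2)
    pairs = []
    for c1, c2 in matched:
        fwd, rev = (c1, c2) if c1.strand == "+" else (c2, c1)
        pairs.append(CandidatePair(fwd=fwd, rev=rev,
                                   mate_distance=mate_distance(fwd, rev)))
    mate1_ids = {id(c) for c in mate1}
    for c in orphans:
        missing_mate = 2 if id(c) in mate1_ids else 1
        pairs.append(orphan_to_pair(c, cfg.penalties,
                                    unmapped_quals.get(missing_mate)))
    if not pairs:
        return None
    group = PairGroup(read_name=records[0].query_name, pairs=pairs)
    pe_posteriors(group, frag_model, cfg.penalties)
    return select_best(group, cfg.penalties)


_SECONDARY = 0x100


def _annotate_record(cand: CandidateAlignment, n_candidates: int,
                     primary: bool) -> pysam.AlignedSegment:
    rec = cand.record
    rec.mapping_quality = int(cand.mapq)
    if primary:
        rec.flag &= ~_SECONDARY
    else:
        rec.flag |= _SECONDARY
    rec.set_tag("XL", float(cand.log_lik), value_type="f")
    rec.set_tag("XP", float(cand.posterior), value_type="f")
    rec.set_tag("XN", int(n_candidates))
    rec.set_tag("XM", int(cand.mismatch_count))
    rec.set_tag("XO", int(cand.indel_count))
    return rec


def annotate_and_write(ordered: Sequence, out: pysam.AlignmentFile,
                       cfg: RunConfig) -> int:
    """Write the ranked candidates (or pairs) of one read, primary first.

    The primary record carries the recomputed MAPQ; up to ``max_report``
    further candidates are written flagged secondary.  Records whose mapQ
    falls below ``min_mapq_out`` are dropped (a dropped primary drops the
    read).  Returns the number of records written.
    """
    written = 0
    n = len(ordered)
    for rank, item in enumerate(ordered[:cfg.max_report + 1]):
        primary = rank == 0
        if item.mapq < cfg.min_mapq_out:
            if primary:
                logger.info("dropping read %s: primary mapQ %d < %d",
                            _name_of(item), item.mapq, cfg.min_mapq_out)
                return 0
            continue
        if isinstance(item, CandidatePair):
            for cand in (item.fwd, item.rev):
                if cand.record is None:
                    continue  # synthetic soft-clipped pseudo-mate
                cand.mapq = item.mapq
                cand.posterior = item.posterior
                cand.log_lik = (cand.log_lik if cand.log_lik is not None
                                else item.pair_log_lik)
                rec = _annotate_record(cand, n, primary)
                if item.is_orphan:
                    rec.mate_is_unmapped = True
                out.write(rec)
                written += 1
        else:
            out.write(_annotate_record(item, n, primary))
            written += 1
    return written


def estimate_fragment_model_from_file(path: str, min_n: int = 1000,
                                      max_samples: int = 100000
                                      ) -> FragmentModel:
    """First pass over a name-grouped PE file: collect outer mate distances
    of fragments where each mate has exactly one mapped candidate on the
    same reference, then fit the fragment-size model."""
    distances: list[float] = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for _, records in group_stream(af):
            m1 = [r for r in records if r.is_read1 and not r.is_unmapped]
            m2 = [r for r in records
                  if (r.is_read2 or not r.is_read1) and not r.is_unmapped]
            if len(m1) != 1 or len(m2) != 1:
                continue
            a, b = m1[0], m2[0]
            if a.reference_id != b.reference_id:
                continue
            if a.is_reverse == b.is_reverse:
                continue
            d = (max(a.reference_end, b.reference_end)
                 - min(a.reference_start, b.reference_start))
            distances.append(float(d))
            if len(distances) >= max_samples:
                break
    return estimate_fragment_model(distances, min_n=min_n)


def _name_of(item) -> str:
    return item.read_name


def _open_out(path: str, template_header: pysam.AlignmentHeader,
              command_line: str) -> pysam.AlignmentFile:
    head = template_header.to_dict()
    head.setdefault("PG", []).append({
        "ID": "remapq", "PN": "remapq", "VN": __version__,
        "CL": command_line})
    mode = "wb" if path.endswith(".bam") else "w"
    return pysam.AlignmentFile(path, mode, header=head)


def filter_file(in_path: str, out_path: str, cfg: RunConfig,
                command_line: str = "remapq filter") -> dict:
    """Run the full posterior filtering pipeline on one SAM/BAM file.

    PE mode makes two passes: the first estimates the fragment-size model
    from uniquely-mapped concordant pairs, the second scores and writes.
    Unmapped-only reads pass through untouched.  Returns summary counters.
    """
    variants = (KnownVariantIndex.from_vcf(cfg.variant_vcf)
                if cfg.variant_vcf else None)
    frag_model = FragmentModel()
    if cfg.mode == "PE":
        frag_model = estimate_fragment_model_from_file(
            in_path, min_n=cfg.min_frag_n)
        logger.info("fragment model: mean=%.1f sd=%.1f n=%d reliable=%s",
                    frag_model.mean, frag_model.sd, frag_model.n,
                    frag_model.reliable)

    stats = {"groups": 0, "written": 0, "dropped": 0, "passthrough": 0}
    with pysam.AlignmentFile(in_path, check_sq=False) as af:
        with _open_out(out_path, af.header, command_line) as out:
            for name, records in group_stream(af):
                stats["groups"] += 1
                if all(r.is_unmapped for r in records):
                    for r in records:
                        out.write(r)
                    stats["passthrough"] += 1
                    continue
                if cfg.mode == "SE":
                    ordered = process_se_group(records, cfg, variants)
                else:
                    ordered = process_pe_group(records, cfg, frag_model,
                                               variants)
                if ordered is None:
                    stats["dropped"] += 1
                    logger.info("read %s: no scoreable candidates", name)
                    continue
                n = annotate_and_write(ordered, out, cfg)
                stats["written"] += n
                if n == 0:
                    stats["dropped"] += 1
    logger.info("processed %(groups)d groups: %(written)d records written, "
                "%(dropped)d reads dropped, %(passthrough)d unmapped "
                "passed through", stats)
    return stats
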