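"""Log10 alignment likelihoods, plain and known-variant aware.

The likelihood of a candidate alignment is the per-position product of base
probabilities, computed in log10 space.  A matched base contributes
``lg(1 - q2p(Q))``; a mismatch contributes ``Q/s`` (with ``s = -10``);
gaps and clips additionally subtract a status-specific penalty gamma.

When a VCF of known variants is supplied, an apparent mismatch (or indel)
that coincides with a known alternate allele may instead be scored as a
correctly-sequenced polymorphism, penalised only by the variant prior
``gamma`` (or ``-lg(AF_alt)`` when an allele frequency is available).  For
each known variant the larger of the plain and variant-aware contribution
is kept, treating variants as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pysam

from .model import (
    AlignmentStatus,
    CandidateAlignment,
    PenaltyConfig,
    estimate_clip_quality,
)

logger = logging.getLogger(__name__)

_CINS, _CDEL = 1, 2

# error probability floor so lg(1-p) stays finite for Q=0 bases
_MAX_ERR = 1.0 - 1e-12


def q2p(q):
    """Convert phred quality to error probability, ``10**(-q/10)``."""
    q = np.asarray(q, dtype=np.float64)
    if np.any(q < 0):
        raise ValueError("phred quality must be non-negative")
    return 10.0 ** (-q / 10.0)


def af_penalty(af: float) -> float:
    """Penalty for a known variant with allele frequency ``af``:
    ``-lg(af)``, non-negative for af in (0, 1]."""
    if not 0.0 < af <= 1.0:
        raise ValueError("allele frequency must be in (0, 1]")
    return float(-np.log10(af))


def _status_contributions(candidate: CandidateAlignment,
                          config: PenaltyConfig) -> np.ndarray:
    """Per-position log10 contributions under the plain model."""
    if np.isnan(candidate.qualities).any():
        estimate_clip_quality(candidate, config)
    st = candidate.statuses
    q = candidate.qualities
    qs = -q / 10.0  # Q/s with s = -10
    perr = np.minimum(q2p(q), _MAX_ERR)
    out = np.zeros(len(st), dtype=np.float64)
    m = st == AlignmentStatus.MATCH
    out[m] = np.log10(1.0 - perr[m])
    m = st == AlignmentStatus.MISMATCH
    out[m] = qs[m]
    m = st == AlignmentStatus.GAP_OPEN
    out[m] = qs[m] - config.gamma_open
    m = st == AlignmentStatus.GAP_EXT
    out[m] = qs[m] - config.gamma_ext
    m = st == AlignmentStatus.SOFT_CLIP
    out[m] = qs[m] - config.gamma_soft
    m = st == AlignmentStatus.HARD_CLIP
    out[m] = qs[m] - config.gamma_hard
    # IGNORED positions stay 0
    return out


def log_likelihood(candidate: CandidateAlignment,
                   config: PenaltyConfig) -> float:
    """Plain log10 alignment likelihood; stored on the candidate."""
    ll = float(np.sum(_status_contributions(candidate, config)))
    candidate.log_lik = ll
    return ll


@dataclass(frozen=True)
class KnownVariant:
    """One known variant, normalised to the changed bases only.

    ``position`` is the 0-based coordinate of the first changed base
    (for insertions: the reference base *before* which the sequence is
    inserted).  ``ref_allele``/``alt_allele`` are the changed sequences with
    the shared VCF anchor stripped; an insertion has an empty ref allele, a
    deletion an empty alt allele.
    """

    reference_name: str
    position: int
    kind: Literal["SNV", "INDEL", "MNP"]
    ref_allele: str
    alt_allele: str
    alt_af: Optional[float] = None

    def __post_init__(self):
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("variant must change at least one base")
        if self.alt_af is not None and not 0.0 < self.alt_af <= 1.0:
            raise ValueError("alt_af must be in (0, 1]")

    def gamma(self, config: PenaltyConfig) -> float:
        if self.alt_af is not None:
            return af_penalty(self.alt_af)
        return {"SNV": config.gamma_snp,
                "INDEL": config.gamma_indel,
                "MNP": config.gamma_mnp}[self.kind]


def _normalise(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Strip the shared prefix (VCF anchor) and suffix from an allele pair."""
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt, pos


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNP"
    return "INDEL"


class KnownVariantIndex:
    """Known variants indexed by (reference_name, position).

    SNVs and MNPs are keyed by the position of their first changed base;
    indels by the left-aligned position of the first inserted/deleted base,
    exactly as they appear (left-aligned) in the source VCF.
    """

    def __init__(self, variants: Optional[list[KnownVariant]] = None):
        self._by_pos: dict[tuple[str, int], list[KnownVariant]] = {}
        for v in variants or []:
            self.add(v)

    def add(self, variant: KnownVariant) -> None:
        key = (variant.reference_name, variant.position)
        self._by_pos.setdefault(key, []).append(variant)

    def lookup(self, reference_name: str, position: int) -> list[KnownVariant]:
        return self._by_pos.get((reference_name, int(position)), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pos.values())

    @classmethod
    def from_vcf(cls, path: str) -> "KnownVariantIndex":
        """Load variants from a VCF/gVCF file.

        Multi-allelic records expand to one variant per alternate allele,
        with per-allele AF taken from INFO/AF when present.  Symbolic
        alleles and breakends are skipped with a warning.
        """
        index = cls()
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                afs = rec.info.get("AF") if "AF" in rec.info else None
                if afs is not None and not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                alts = rec.alts or ()
                for i, alt in enumerate(alts):
                    if alt is None or any(c in alt for c in "<>[]*."):
                        logger.warning(
                            "skipping symbolic/breakend allele %s at %s:%d",
                            alt, rec.chrom, rec.pos)
                        continue
                    ref, alt_n, pos = _normalise(rec.ref.upper(), alt.upper(),
                                                 rec.start)
                    if not ref and not alt_n:
                        continue
                    af = None
                    if afs is not None and i < len(afs) and afs[i] is not None:
                        af = float(afs[i])
                        if not 0.0 < af <= 1.0:
                            af = None
                    index.add(KnownVariant(rec.chrom, pos,
                                           classify_variant(ref, alt_n),
                                           ref, alt_n, af))
        return index


def _mismatch_blocks(candidate: CandidateAlignment) -> list[tuple[int, int]]:
    """Maximal runs of consecutive expanded indices with MISMATCH status
    covering consecutive reference positions."""
    idx = np.flatnonzero(candidate.statuses == AlignmentStatus.MISMATCH)
    blocks = []
    i = 0
    while i < len(idx):
        j = i
        while (j + 1 < len(idx) and idx[j + 1] == idx[j] + 1
               and candidate.ref_pos[idx[j + 1]] == candidate.ref_pos[idx[j]] + 1):
            j += 1
        blocks.append((int(idx[i]), int(idx[j]) + 1))
        i = j + 1
    return blocks


def log_likelihood_variant_aware(candidate: CandidateAlignment,
                                 variants: KnownVariantIndex,
                                 config: PenaltyConfig,
                                 strict_literal: bool = False) -> float:
    """Variant-aware log10 likelihood.

    Every apparent difference from the reference that matches a known
    alternate allele is scored both ways — as a sequencing error (plain) and
    as a true polymorphism penalised by the variant prior — and the larger
    contribution is kept.  Variants are treated independently; positions
    already re-scored by one variant are not re-scored by another.

    With ``strict_literal=True`` the polymorphism term keeps the mismatch
    error factor (``Q/s - gamma`` instead of ``lg(1-q2p(Q)) - gamma``),
    which can never beat the plain term for point variants; the flag exists
    to compare the two readings of the scoring rule.
    """
    contrib = _status_contributions(candidate, config)
    total = float(np.sum(contrib))
    chrom = candidate.reference_name
    q = candidate.qualities
    used = np.zeros(len(contrib), dtype=bool)

    def seq_term(sl: slice) -> float:
        """log10 prob that the bases in ``sl`` were sequenced correctly."""
        if strict_literal:
            return float(np.sum(-q[sl] / 10.0))
        perr = np.minimum(q2p(q[sl]), _MAX_ERR)
        return float(np.sum(np.log10(1.0 - perr)))

    # --- point variants (SNV whole blocks of length 1, MNP whole blocks) ---
    for b0, b1 in _mismatch_blocks(candidate):
        for start in range(b0, b1):
            pos = int(candidate.ref_pos[start])
            for var in sorted(variants.lookup(chrom, pos),
                              key=lambda v: (v.kind, v.alt_allele)):
                if var.kind == "INDEL":
                    continue
                m = len(var.alt_allele)
                end = start + m
                if end > b1 or used[start:end].any():
                    continue
                read = "".join(candidate.read_bases[start:end])
                if read.upper() != var.alt_allele:
                    continue
                ref = "".join(candidate.ref_bases[start:end]).upper()
                if ref and len(ref) == m and ref != var.ref_allele:
                    logger.warning(
                        "known %s at %s:%d: VCF ref %s disagrees with "
                        "alignment reference %s; variant skipped",
                        var.kind, chrom, pos, var.ref_allele, ref)
                    continue
                sl = slice(start, end)
                plain = float(np.sum(contrib[sl]))
                aware = seq_term(sl) - var.gamma(config)
                if aware > plain:
                    total += aware - plain
                    used[sl] = True
                    break

    # --- indel runs ---
    for start, end, is_ins in _indel_runs(candidate):
        if used[start:end].any():
            continue
        if is_ins:
            pos = _insertion_point(candidate, end)
            observed = "".join(candidate.read_bases[start:end]).upper()
        else:
            pos = int(candidate.ref_pos[start])
            observed = "".join(candidate.ref_bases[start:end]).upper()
        for var in variants.lookup(chrom, pos):
            if var.kind != "INDEL":
                continue
            want_ins = var.ref_allele == ""
            if want_ins != is_ins:
                continue
            target = var.alt_allele if is_ins else var.ref_allele
            if len(target) != end - start:
                continue
            if observed.strip() and observed != target:
                continue
            sl = slice(start, end)
            plain = float(np.sum(contrib[sl]))
            m = end - start
            if strict_literal:
                aware = float(np.sum(-q[sl] / 10.0)) - m * var.gamma(config)
            else:
                # one run-level variant penalty replaces the gap penalties;
                # the per-base quality factors are kept
                aware = float(np.sum(-q[sl] / 10.0)) - var.gamma(config)
            if aware > plain:
                total += aware - plain
                used[sl] = True
                break

    candidate.log_lik = total
    return total


def _indel_runs(candidate: CandidateAlignment) -> list[tuple[int, int, bool]]:
    """(start, end, is_insertion) for each I or D run of expanded indices."""
    runs = []
    ops = candidate.ops
    n = len(ops)
    i = 0
    while i < n:
        if ops[i] in (_CINS, _CDEL):
            j = i
            while j < n and ops[j] == ops[i]:
                j += 1
            runs.append((i, j, ops[i] == _CINS))
            i = j
        else:
            i += 1
    return runs


def _insertion_point(candidate: CandidateAlignment, run_end: int) -> int:
    """Reference position before which an insertion run sits (the position
    of the next reference-consuming base)."""
    after = candidate.ref_pos[run_end:]
    after = after[after >= 0]
    if len(after):
        return int(after[0])
    before = candidate.ref_pos[:run_end]
    before = before[before >= 0]
    return int(before[-1]) + 1 if len(before) else candidate.end
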