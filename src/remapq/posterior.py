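"""Posterior mapping probabilities and phred-scaled mapQ.

For a single-end read with candidate set A, the posterior of candidate i is

    Pr(map_i | A) = L_i * 10**ll_i / sum_k L_k * 10**ll_k

where ``L_i`` is the alignment length (the locus prior is proportional to
alignment length; the effective-genome-size denominator cancels) and
``ll_i`` the log10 alignment likelihood.  mapQ is the phred-scaled
probability that the mapping is wrong: ``-10*lg(1 - posterior)``.

Paired-end candidates are scored jointly: the pair posterior is
proportional to ``L_fwd * L_rev * 10**(ll_fwd + ll_rev) * Pr_pair(d)``,
where the pairing probability is a Gaussian density of the mate distance
when the fragment-size distribution can be estimated reliably, and a
constant otherwise.  A missing mate is replaced by a pseudo-mate whose
every base is soft-clipped, so orphan and concordant candidates compete in
one normalisation pool without systematically favouring either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .model import (
    AlignmentStatus,
    CandidateAlignment,
    PenaltyConfig,
    ReadGroup,
)

_CSOFT = 4


@dataclass
class FragmentModel:
    """Fragment (insert) size distribution of properly-paired reads."""

    mean: float = 0.0
    sd: float = 0.0
    reliable: bool = False
    constant_density: float = 1.0
    n: int = 0

    def __post_init__(self) -> None:
        if self.reliable and self.sd <= 0:
            raise ValueError("a reliable model requires sd > 0")
        if self.constant_density <= 0:
            raise ValueError("constant_density must be positive")


@dataclass
class CandidatePair:
    """One candidate placement of a read pair (possibly with a synthetic
    soft-clipped pseudo-mate when only one mate mapped at this locus)."""

    fwd: CandidateAlignment
    rev: CandidateAlignment
    mate_distance: Optional[int] = None
    is_orphan: bool = False
    pair_log_lik: Optional[float] = None
    posterior: Optional[float] = None
    mapq: Optional[int] = None
    is_primary: bool = False

    @property
    def read_name(self) -> str:
        return self.fwd.read_name

    def locus(self) -> tuple:
        return (self.fwd.reference_name, self.fwd.start, self.fwd.strand,
                self.rev.reference_name, self.rev.start, self.rev.strand)


@dataclass
class PairGroup:
    """All candidate pairs of one fragment; the PE normalisation unit."""

    read_name: str
    pairs: list[CandidatePair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("PairGroup requires at least one pair")


def mapq(posterior: float, config: PenaltyConfig) -> int:
    """Phred-scale a posterior: ``round(-10*lg(1 - posterior))``, rounded
    half-up and capped at ``config.mapq_cap``."""
    if not 0.0 <= posterior <= 1.0:
        raise ValueError("posterior must be in [0, 1]")
    wrong = 1.0 - posterior
    if wrong <= 0.0:
        return config.mapq_cap
    q = -10.0 * math.log10(wrong)
    return min(int(math.floor(q + 0.5)), config.mapq_cap)


def _normalise_log10(weights: np.ndarray) -> np.ndarray:
    """Posteriors from log10 weights, stably via max subtraction."""
    m = np.max(weights)
    lin = 10.0 ** (weights - m)
    return lin / np.sum(lin)


def se_posteriors(group: ReadGroup, config: PenaltyConfig) -> ReadGroup:
    """Compute posteriors for every candidate of a single-end read group.

    Candidates must already carry ``log_lik``.  Posteriors are stored on
    the candidates and sum to 1 over the group.
    """
    cands = group.candidates
    if any(c.log_lik is None for c in cands):
        raise ValueError("all candidates need log_lik before se_posteriors")
    w = np.array([math.log10(c.align_length) + c.log_lik for c in cands])
    post = _normalise_log10(w)
    for c, p in zip(cands, post):
        c.posterior = float(p)
        c.mapq = mapq(float(p), config)
    return group


def estimate_fragment_model(distances: Iterable[float],
                            min_n: int = 1000,
                            constant_density: float = 1.0,
                            max_cv: float = 2.0) -> FragmentModel:
    """Estimate the fragment-size distribution from mate distances of
    uniquely-mapped concordant pairs.

    The model is flagged ``reliable`` only when at least ``min_n`` distances
    were seen and the spread is sane (sd > 0 and sd/mean < ``max_cv``);
    otherwise downstream pairing uses a constant density.
    """
    d = np.asarray(list(distances), dtype=np.float64)
    n = len(d)
    if n == 0:
        return FragmentModel(constant_density=constant_density, n=0)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    reliable = (n >= min_n and sd > 0.0 and mean > 0.0
                and sd / mean < max_cv)
    return FragmentModel(mean=mean, sd=sd, reliable=reliable,
                         constant_density=constant_density, n=n)


def pairing_density(d_mate: float, model: FragmentModel) -> float:
    """Pairing probability of a mate distance: Gaussian density under a
    reliable fragment model, the configured constant otherwise."""
    if not model.reliable:
        return model.constant_density
    z = (d_mate - model.mean) / model.sd
    return math.exp(-0.5 * z * z) / (model.sd * math.sqrt(2.0 * math.pi))


def mate_distance(fwd: CandidateAlignment,
                  rev: CandidateAlignment) -> Optional[int]:
    """Outer mate distance (TLEN convention): rightmost end minus leftmost
    start of the pair.  None when the mates sit on different references."""
    if fwd.reference_name != rev.reference_name:
        return None
    return max(fwd.end, rev.end) - min(fwd.start, rev.start)


def pe_posteriors(group: PairGroup, model: FragmentModel,
                  config: PenaltyConfig) -> PairGroup:
    """Compute joint posteriors for every candidate pair of a fragment.

    Orphan pairs (synthetic soft-clipped mate) and cross-reference pairs
    use the constant pairing density; concordant pairs use the Gaussian
    density when the fragment model is reliable.
    """
    pairs = group.pairs
    w = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        if p.fwd.log_lik is None or p.rev.log_lik is None:
            raise ValueError("mates need log_lik before pe_posteriors")
        if p.mate_distance is None and not p.is_orphan:
            p.mate_distance = mate_distance(p.fwd, p.rev)
        if p.is_orphan or p.mate_distance is None:
            dens = model.constant_density
        else:
            dens = pairing_density(p.mate_distance, model)
        p.pair_log_lik = p.fwd.log_lik + p.rev.log_lik
        w[i] = (math.log10(p.fwd.align_length)
                + math.log10(p.rev.align_length)
                + p.pair_log_lik
                + math.log10(max(dens, 1e-300)))
    post = _normalise_log10(w)
    for p, pp in zip(pairs, post):
        p.posterior = float(pp)
        p.mapq = mapq(float(pp), config)
    return group


def make_soft_clipped_mate(read_name: str,
                           reference_name: str,
                           start: int,
                           strand: str,
                           qualities: Sequence[float]) -> CandidateAlignment:
    """Build a pseudo-alignment whose every base is soft-clipped, used to
    stand in for a missing mate."""
    n = len(qualities)
    if n == 0:
        raise ValueError("pseudo-mate needs at least one base")
    return CandidateAlignment(
        read_name=read_name,
        reference_name=reference_name,
        start=start,
        end=start,
        strand=strand,
        ops=np.full(n, _CSOFT, dtype=np.uint8),
        statuses=np.full(n, AlignmentStatus.SOFT_CLIP, dtype=np.uint8),
        qualities=np.asarray(qualities, dtype=np.float64),
        read_bases=np.full(n, "N", dtype="U1"),
        ref_bases=np.full(n, "", dtype="U1"),
        ref_pos=np.full(n, -1, dtype=np.int64),
        read_pos=np.arange(n, dtype=np.int64),
        align_length=n,
        mismatch_count=0,
        indel_count=0,
    )


def orphan_to_pair(mapped: CandidateAlignment,
                   config: PenaltyConfig,
                   mate_qualities: Optional[Sequence[float]] = None) -> CandidatePair:
    """Pair a candidate whose mate has no alignment at this locus with a
    fully soft-clipped pseudo-mate.

    When the unmapped mate's record is available its own base qualities are
    used; otherwise the pseudo-mate takes the mapped mate's length and mean
    quality.  The resulting pair is scored with the constant pairing
    density.
    """
    if mate_qualities is None or len(mate_qualities) == 0:
        obs = mapped.qualities[~np.isnan(mapped.qualities)]
        mean_q = float(np.mean(obs)) if len(obs) else 20.0
        mate_qualities = [mean_q] * mapped.align_length
    pseudo = make_soft_clipped_mate(
        mapped.read_name, mapped.reference_name, mapped.start,
        "-" if mapped.strand == "+" else "+", mate_qualities)
    # score the pseudo-mate: every base soft-clipped
    pseudo.log_lik = float(
        np.sum(-np.asarray(mate_qualities, dtype=np.float64) / 10.0
               - config.gamma_soft))
    fwd, rev = (mapped, pseudo) if mapped.strand == "+" else (pseudo, mapped)
    return CandidatePair(fwd=fwd, rev=rev, is_orphan=True)


def select_best(group: Union[ReadGroup, PairGroup],
                config: PenaltyConfig) -> list:
    """Order candidates by posterior (descending) and mark the best primary.

    Ties are broken deterministically by locus (reference name, start,
    strand), lexicographically smallest first, so repeated runs always pick
    the same primary.  Returns the ordered candidate (or pair) list.
    """
    items = group.candidates if isinstance(group, ReadGroup) else group.pairs
    if any(it.posterior is None for it in items):
        raise ValueError("posteriors must be computed before select_best")
    ordered = sorted(items, key=lambda it: (-it.posterior, it.locus()))
    for i, it in enumerate(ordered):
        it.is_primary = i == 0
        if it.mapq is None:
            it.mapq = mapq(it.posterior, config)
    return ordered
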