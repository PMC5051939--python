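"""Synthetic NGS read simulation with a positional quality-decay model.

Reads are drawn from random genomic regions (uniform locations, truncated
Gaussian sizes, optionally restricted to BED features).  Base qualities are
Gaussian per position with a fixed mean over an initial seed region and a
linearly decreasing mean afterwards, independently for forward and reverse
reads.  Sequencing errors are then introduced base-by-base with probability
``10**(-Q/10)`` and split between substitutions, insertions and deletions.
The true origin of each read is encoded losslessly in its name, so no
sidecar truth file is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO

import numpy as np
from scipy import stats

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = "ACGT"

QUAL_MIN, QUAL_MAX = 2, 41  # Illumina-like phred clamp


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of the read simulator.

    Region sizes are truncated-Gaussian in
    ``[region_size_min, region_size_max]``.  Base-quality means stay at
    ``seed_quality_mean`` for the first ``seed_length`` bases and then
    decrease by ``quality_decay`` phred per base.  Mutation fractions must
    sum to 1.
    """

    region_size_mean: float = 300.0
    region_size_sd: float = 50.0
    region_size_min: float = 150.0
    region_size_max: float = 500.0
    read_length: int = 100
    paired: bool = False
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    seed_length: int = 25
    seed_quality_mean: float = 35.0
    quality_decay: float = 0.2
    quality_sd: float = 2.0
    sub_fraction: float = 0.90
    ins_fraction: float = 0.05
    del_fraction: float = 0.05

    def __post_init__(self) -> None:
        total = self.sub_fraction + self.ins_fraction + self.del_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mutation fractions must sum to 1")
        if self.region_size_min <= 0 or self.region_size_max < self.region_size_min:
            raise ValueError("invalid region size truncation bounds")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass(frozen=True)
class SimTruth:
    """True origin of a simulated read, encoded in its name as
    ``label:ref:start-end:strand`` (0-based half-open)."""

    label: str
    reference_name: str
    start: int
    end: int
    strand: str

    def encode(self) -> str:
        return (f"{self.label}:{self.reference_name}:"
                f"{self.start}-{self.end}:{self.strand}")

    @classmethod
    def decode(cls, read_name: str) -> "SimTruth":
        label, ref, span, strand = read_name.rsplit(":", 3)
        start, end = span.split("-")
        return cls(label, ref, int(start), int(end), strand)


@dataclass
class SimulatedRead:
    truth: SimTruth
    sequence: str
    qualities: list[int]
    mate: int = 0  # 0 = single-end, 1/2 = paired mates

    @property
    def name(self) -> str:
        return self.truth.encode()


def sample_regions(genome: Mapping[str, str],
                   n: int,
                   config: SimConfig,
                   rng: np.random.Generator,
                   features: Optional[Sequence[tuple[str, int, int]]] = None,
                   ) -> list[tuple[str, int, int]]:
    """Draw ``n`` genomic intervals with uniform starts and truncated-
    Gaussian sizes.

    Without ``features``, starts are uniform over the whole genome
    (chromosomes weighted by length).  With ``features`` (BED-like
    (chrom, start, end) triples), starts are uniform over the feature
    intervals.  Intervals overflowing a chromosome end are resampled.
    """
    if not genome:
        raise ValueError("genome is empty")
    names = list(genome)
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    if features is not None:
        if not features:
            raise ValueError("feature list is empty")
        feat = list(features)
        fl = np.array([e - s for _, s, e in feat], dtype=float)
        if fl.max() + 0 < 1:
            raise ValueError("features have zero length")
        max_room = max(len(genome[c]) - s for c, s, _ in feat)
        if max_room < config.region_size_min:
            raise ValueError("no feature interval can hold the minimum "
                             "region size")

    a = (config.region_size_min - config.region_size_mean) / config.region_size_sd
    b = (config.region_size_max - config.region_size_mean) / config.region_size_sd
    dist = stats.truncnorm(a, b, loc=config.region_size_mean,
                           scale=config.region_size_sd)

    regions: list[tuple[str, int, int]] = []
    max_tries = 1000 * max(n, 1)
    tries = 0
    while len(regions) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place regions; genome or features "
                               "too small for the configured region sizes")
        size = int(round(dist.rvs(random_state=rng)))
        if features is None:
            ci = rng.choice(len(names), p=lengths / lengths.sum())
            chrom = names[ci]
            room = len(genome[chrom]) - size
            if room < 0:
                continue
            start = int(rng.integers(0, room + 1))
        else:
            fi = rng.choice(len(feat), p=fl / fl.sum())
            chrom, fs, fe = feat[fi]
            start = int(rng.integers(fs, fe))
            if start + size > len(genome[chrom]):
                continue
        regions.append((chrom, start, start + size))
    return regions


def simulate_qualities(read_length: int,
                       config: SimConfig,
                       rng: np.random.Generator) -> list[int]:
    """Per-position phred qualities: Gaussian around a seed-then-linear-
    decay mean profile, clamped to [2, 41].  Forward and reverse reads each
    call this independently."""
    j = np.arange(read_length)
    means = np.where(
        j < config.seed_length,
        config.seed_quality_mean,
        config.seed_quality_mean
        - config.quality_decay * (j - config.seed_length + 1))
    q = rng.normal(means, config.quality_sd)
    q = np.clip(np.rint(q), QUAL_MIN, QUAL_MAX).astype(int)
    return q.tolist()


def mutate_read(sequence: str,
                qualities: Sequence[int],
                config: SimConfig,
                rng: np.random.Generator) -> tuple[str, list[int]]:
    """Mutate each base with probability ``10**(-Q/10)``.

    A mutation is a substitution, insertion or deletion with the configured
    fractions.  Substitutions pick uniformly among the three other bases;
    insertions add a random base after the position (inheriting its
    quality); deletions remove the base.  Qualities track the edits.
    """
    if len(sequence) != len(qualities):
        raise ValueError("sequence and qualities must have equal length")
    out_seq: list[str] = []
    out_q: list[int] = []
    cuts = (config.sub_fraction, config.sub_fraction + config.ins_fraction)
    for base, q in zip(sequence, qualities):
        if rng.random() >= 10.0 ** (-q / 10.0):
            out_seq.append(base)
            out_q.append(q)
            continue
        r = rng.random()
        if r < cuts[0]:  # substitution
            others = [b for b in _BASES if b != base.upper()]
            out_seq.append(others[rng.integers(0, 3)])
            out_q.append(q)
        elif r < cuts[1]:  # insertion after this base
            out_seq.append(base)
            out_q.append(q)
            out_seq.append(_BASES[rng.integers(0, 4)])
            out_q.append(q)
        # deletion: emit nothing
    return "".join(out_seq), out_q


def simulate_reads(genome: Mapping[str, str],
                   n: int,
                   config: SimConfig,
                   rng: np.random.Generator,
                   features: Optional[Sequence[tuple[str, int, int]]] = None,
                   ) -> Iterator[SimulatedRead]:
    """Simulate ``n`` fragments and yield reads (one per fragment for SE,
    two mates per fragment for PE).

    The truth interval of each read is the genomic span it was copied from
    before mutation; for paired reads mate 1 comes from the 5' fragment end
    on the fragment strand and mate 2 from the 3' end on the opposite
    strand.
    """
    rl = config.read_length
    regions = sample_regions(genome, n, config, rng, features=features)
    for i, (chrom, rstart, rend) in enumerate(regions):
        strand = "+" if rng.random() < 0.5 else "-"
        if config.paired:
            for mate in (1, 2):
                if (strand == "+") == (mate == 1):
                    g0, g1, s = rstart, rstart + rl, "+"
                else:
                    g0, g1, s = rend - rl, rend, "-"
                raw = genome[chrom][g0:g1].upper()
                if s == "-":
                    raw = revcomp(raw)
                quals = simulate_qualities(rl, config, rng)
                seq, quals = mutate_read(raw, quals, config, rng)
                truth = SimTruth(f"f{i}/{mate}", chrom, g0, g1, s)
                yield SimulatedRead(truth, seq, quals, mate=mate)
        else:
            if strand == "+":
                g0, g1 = rstart, rstart + rl
            else:
                g0, g1 = rend - rl, rend
            raw = genome[chrom][g0:g1].upper()
            if strand == "-":
                raw = revcomp(raw)
            quals = simulate_qualities(rl, config, rng)
            seq, quals = mutate_read(raw, quals, config, rng)
            truth = SimTruth(f"r{i}", chrom, g0, g1, strand)
            yield SimulatedRead(truth, seq, quals)


def write_fastq(reads: Iterable[SimulatedRead], handle: TextIO) -> int:
    """Write reads as FASTQ (phred+33); returns the number written."""
    count = 0
    for read in reads:
        qstr = "".join(chr(q + 33) for q in read.qualities)
        handle.write(f"@{read.name}\n{read.sequence}\n+\n{qstr}\n")
        count += 1
    return count


def random_genome(size: int, rng: np.random.Generator,
                  name: str = "chr1") -> dict[str, str]:
    """A uniform-random single-chromosome genome."""
    seq = "".join(np.array(list(_BASES))[rng.integers(0, 4, size)])
    return {name: seq}


def plant_duplications(genome: dict[str, str],
                       rng: np.random.Generator,
                       n_dups: int = 10,
                       dup_length: int = 2000,
                       identity: float = 0.95) -> dict[str, str]:
    """Overwrite random target windows with diverged copies of random
    source windows (per-base substitution rate ``1 - identity``), creating
    the segmental duplications that make reads multi-map."""
    out = {}
    for chrom, seq in genome.items():
        arr = list(seq)
        size = len(arr)
        for _ in range(n_dups):
            src = int(rng.integers(0, size - dup_length))
            dst = int(rng.integers(0, size - dup_length))
            copy = list(seq[src:src + dup_length])
            for j in range(dup_length):
                if rng.random() < 1.0 - identity:
                    others = [b for b in _BASES if b != copy[j].upper()]
                    copy[j] = others[rng.integers(0, 3)]
            arr[dst:dst + dup_length] = copy
        out[chrom] = "".join(arr)
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA file into a name -> sequence dict."""
    import pyfaidx

    with pyfaidx.Fasta(path, as_raw=True, rebuild=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], handle: TextIO,
                width: int = 70) -> None:
    for name, seq in genome.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")


def read_fastq(handle: TextIO) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (name, sequence, qualities) from a FASTQ stream."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().strip()
        handle.readline()
        qual = handle.readline().strip()
        yield header.strip()[1:], seq, [ord(c) - 33 for c in qual]
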