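import numpy as np
import pysam
import pytest

from remapq.model import PenaltyConfig

BASES = "ACGT"


@pytest.fixture(scope="session")
def header():
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000},
               {"SN": "chr2", "LN": 1_000_000}],
    })


@pytest.fixture
def config():
    return PenaltyConfig()


@pytest.fixture
def make_record(header):
    """Factory for mapped SAM records with explicit CIGAR/MD/qualities."""

    def build(cigar, md=None, seq=None, quals=None, start=100, name="read1",
              reverse=False, chrom="chr1", flag_extra=0):
        import re
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        read_len = sum(int(n) for n, op in
                       re.findall(r"(\d+)([MIS=X])", cigar))
        rec.query_sequence = seq if seq is not None else "A" * read_len
        rec.query_qualities = quals if quals is not None else [20] * read_len
        rec.reference_id = header.get_tid(chrom)
        rec.reference_start = start
        rec.cigarstring = cigar
        rec.flag = (16 if reverse else 0) | flag_extra
        if md is not None:
            rec.set_tag("MD", md)
        return rec

    return build


def random_alignment(rng, header, name="r", chrom="chr1", start=None,
                     mismatch_p=0.1, max_core=60, allow_clips=True):
    """Build a random but internally consistent mapped record together with
    the expected canonical CIGAR and MD strings.

    The alignment core alternates aligned blocks with occasional insertions,
    deletions and reference skips; optional soft/hard clips flank it.
    Returns (record, cigar, md, n_mismatches, n_indel_runs).
    """
    if start is None:
        start = int(rng.integers(0, 10_000))
    ops = []  # (op_char, length)
    if allow_clips and rng.random() < 0.3:
        ops.append(("H", int(rng.integers(1, 5))))
    if allow_clips and rng.random() < 0.4:
        ops.append(("S", int(rng.integers(1, 8))))
    n_blocks = int(rng.integers(1, 4))
    for b in range(n_blocks):
        ops.append(("M", int(rng.integers(1, max_core // n_blocks + 1))))
        if b < n_blocks - 1:
            kind = rng.choice(["I", "D", "N"])
            ops.append((kind, int(rng.integers(1, 6))))
    if allow_clips and rng.random() < 0.4:
        ops.append(("S", int(rng.integers(1, 8))))
    if allow_clips and ops[0][0] == "H" and rng.random() < 0.5:
        ops.append(("H", int(rng.integers(1, 5))))

    seq_parts, md_parts = [], []
    run = 0
    n_mm = 0
    n_indel = 0
    for op, length in ops:
        if op == "M":
            for _ in range(length):
                base = BASES[rng.integers(0, 4)]
                if rng.random() < mismatch_p:
                    ref = BASES[(BASES.index(base) + 1 + rng.integers(0, 3)) % 4]
                    md_parts.append(str(run))
                    md_parts.append(ref)
                    run = 0
                    n_mm += 1
                else:
                    run += 1
                seq_parts.append(base)
        elif op == "I":
            seq_parts.extend(BASES[rng.integers(0, 4)] for _ in range(length))
            n_indel += 1
        elif op == "D":
            md_parts.append(str(run))
            run = 0
            md_parts.append("^" + "".join(BASES[rng.integers(0, 4)]
                                          for _ in range(length)))
            n_indel += 1
        elif op == "S":
            seq_parts.extend(BASES[rng.integers(0, 4)] for _ in range(length))
        # N and H consume neither sequence nor MD
    md_parts.append(str(run))
    md = "".join(md_parts)
    cigar = "".join(f"{length}{op}" for op, length in ops)
    seq = "".join(seq_parts)
    quals = [int(q) for q in rng.integers(2, 42, len(seq))]

    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.query_qualities = quals
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = start
    rec.cigarstring = cigar
    rec.set_tag("MD", md)
    return rec, cigar, md, n_mm, n_indel
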