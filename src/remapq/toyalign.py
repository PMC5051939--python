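"""A tiny exhaustive aligner for test fixtures on small genomes.

Reports *every* locus (both strands) where a read aligns with at most
``max_edits`` edits, as SAM records with extended CIGAR (=/X) plus MD and
NM tags — exactly the multi-mapping input the posterior model consumes.

Candidate loci are found by exact k-mer seeding with the pigeonhole
guarantee: a read is split into ``max_edits + 1`` segments, at least one of
which must be edit-free, so its leading k-mer occurs verbatim in the
genome.  Each seed hit is verified by banded edit distance (edlib) in a
window padded by ``max_edits`` on both sides.  The true locus of a read is
therefore always reported when its edit count is within ``max_edits``.
Intended scale is genomes up to ~1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import edlib
import pysam

from .simulate import revcomp

_CIGAR_RE = __import__("re").compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ToyHit:
    reference_name: str
    start: int
    end: int
    strand: str
    edits: int
    cigar: str  # extended (=/X) CIGAR
    md: str


class ToyAligner:
    """Exhaustive small-genome aligner (see module docstring).

    Parameters
    ----------
    genome:
        name -> sequence mapping; indexed once.
    max_edits:
        report every locus with edit distance <= max_edits.
    kmer:
        seed length; reads must satisfy
        ``len(read) >= (max_edits + 1) * kmer`` for the exhaustiveness
        guarantee to hold (enforced).
    """

    def __init__(self, genome: Mapping[str, str], max_edits: int = 6,
                 kmer: int = 9):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.max_edits = max_edits
        self.kmer = kmer
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for pos in range(0, len(seq) - kmer + 1):
                self._index.setdefault(seq[pos:pos + kmer], []).append(
                    (chrom, pos))
        self.header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in self.genome.items()],
        })

    # ------------------------------------------------------------------ hits

    def find_hits(self, seq: str) -> list[ToyHit]:
        """All loci with <= max_edits edits for ``seq``, both strands."""
        hits: dict[tuple, ToyHit] = {}
        for strand, s in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
            for hit in self._scan(s):
                key = (hit.reference_name, strand, hit.start, hit.cigar)
                h = ToyHit(hit.reference_name, hit.start, hit.end, strand,
                           hit.edits, hit.cigar, hit.md)
                if key not in hits:
                    hits[key] = h
        return self._cluster(list(hits.values()))

    def _scan(self, s: str) -> list[ToyHit]:
        e = self.max_edits
        k = self.kmer
        n_seg = e + 1
        seg = len(s) // n_seg
        if seg < k:
            raise ValueError(
                f"read of length {len(s)} too short for max_edits={e} with "
                f"k={k}: needs length >= {n_seg * k}")
        out = []
        seen_windows = set()
        for i in range(n_seg):
            r = i * seg
            for chrom, g in self._index.get(s[r:r + k], ()):
                ws = g - r - e
                wstart = max(ws, 0)
                wend = min(ws + len(s) + 2 * e, len(self.genome[chrom]))
                wkey = (chrom, wstart, wend)
                if wkey in seen_windows:
                    continue
                seen_windows.add(wkey)
                out.extend(self._verify(s, chrom, wstart, wend))
        return out

    def _verify(self, s: str, chrom: str, wstart: int, wend: int) -> list[ToyHit]:
        window = self.genome[chrom][wstart:wend]
        res = edlib.align(s, window, mode="HW", task="path", k=self.max_edits)
        if res["editDistance"] < 0:
            return []
        out = []
        # the reported path belongs to one tie location; re-anchor every
        # location with a global alignment on its exact span
        for (ts, te) in res["locations"]:
            ts = 0 if ts is None else ts
            sub = edlib.align(s, window[ts:te + 1], mode="NW", task="path")
            if sub["editDistance"] > self.max_edits:
                continue
            cigar = sub["cigar"]
            md = _md_from_cigar(cigar, window[ts:te + 1])
            out.append(ToyHit(chrom, wstart + ts, wstart + te + 1, "+",
                              res["editDistance"], cigar, md))
        return out

    def _cluster(self, hits: list[ToyHit]) -> list[ToyHit]:
        """Merge hits of the same strand whose starts lie within max_edits
        (the same locus reached through different seed windows), keeping
        the lowest edit count, ties leftmost."""
        hits.sort(key=lambda h: (h.reference_name, h.strand, h.start,
                                 h.edits))
        merged: list[ToyHit] = []
        for h in hits:
            if (merged
                    and merged[-1].reference_name == h.reference_name
                    and merged[-1].strand == h.strand
                    and abs(h.start - merged[-1].start) <= self.max_edits):
                if h.edits < merged[-1].edits:
                    merged[-1] = h
                continue
            merged.append(h)
        return merged

    # --------------------------------------------------------------- records

    def align(self, name: str, seq: str,
              qualities: Sequence[int]) -> list[pysam.AlignedSegment]:
        """SAM records for every reported locus of one read.

        An unaligned read yields a single unmapped record so the read is
        never silently lost.
        """
        hits = self.find_hits(seq)
        records = []
        for hit in hits:
            rec = pysam.AlignedSegment(self.header)
            rec.query_name = name
            if hit.strand == "-":
                rec.query_sequence = revcomp(seq.upper())
                rec.query_qualities = list(qualities)[::-1]
                rec.flag = 16
            else:
                rec.query_sequence = seq.upper()
                rec.query_qualities = list(qualities)
                rec.flag = 0
            rec.reference_id = self.header.get_tid(hit.reference_name)
            rec.reference_start = hit.start
            rec.cigarstring = hit.cigar
            rec.mapping_quality = 0
            rec.set_tag("MD", hit.md)
            rec.set_tag("NM", hit.edits)
            records.append(rec)
        if not records:
            rec = pysam.AlignedSegment(self.header)
            rec.query_name = name
            rec.flag = 4
            rec.query_sequence = seq.upper()
            rec.query_qualities = list(qualities)
            records.append(rec)
        return records


def toy_align(read: str, genome: Mapping[str, str], max_edits: int,
              kmer: int = 9) -> list[ToyHit]:
    """One-shot convenience wrapper around :class:`ToyAligner`."""
    return ToyAligner(genome, max_edits=max_edits, kmer=kmer).find_hits(read)


def _md_from_cigar(cigar: str, target: str) -> str:
    """Canonical MD string for an extended-CIGAR alignment against the
    aligned slice of the reference."""
    out = []
    run = 0
    t = 0
    for count, op in _CIGAR_RE.findall(cigar):
        count = int(count)
        if op == "=":
            run += count
            t += count
        elif op == "X":
            for _ in range(count):
                out.append(str(run))
                out.append(target[t])
                run = 0
                t += 1
        elif op == "D":
            out.append(str(run))
            run = 0
            out.append("^" + target[t:t + count])
            t += count
        # I consumes the query only
    out.append(str(run))
    return "".join(out)
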