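# remapq

Bayesian recalculation of NGS mapping qualities from *all* candidate
alignments of each read.

Repetitive genomes make many short reads map ambiguously, and most
aligners either discard multi-mapped reads or emit one heuristic "best"
hit with an ad-hoc MAPQ.  remapq instead asks the aligner for every
candidate locus and computes, for each candidate *i* of a read, the
posterior probability that it is the true origin:

    Pr(map_i | A) = L_i · 10^{ll_i} / Σ_k L_k · 10^{ll_k}
    mapQ_i = −10 · lg(1 − Pr(map_i | A))

where *L_i* is the alignment length (the locus prior is proportional to
it) and *ll_i* is a per-base log10 alignment likelihood built from base
qualities and the CIGAR/MD alignment status (match, mismatch, gap, clip).
Paired ends are scored jointly with a Gaussian fragment-size model and a
soft-clipped pseudo-mate standing in for missing mates; known variants
from a VCF can rescue mismatches that are real polymorphisms; and an
optional one-dimensional dynamic program trims each alignment to its
maximum-scoring insert range, rewriting CIGAR and MD consistently.

The package is aimed at people benchmarking or post-processing aligner
output: it bundles a read simulator with a positional quality-decay and
mutation model, a tiny exhaustive aligner for small test genomes, and a
precision/sensitivity/FDR evaluator, so the whole pipeline runs
self-contained.

## Worked example

Simulate 2,000 reads from a 200 kb genome with planted 95%-identity
duplications, report every candidate locus, recompute posteriors and
evaluate:

```python
import numpy as np
from remapq.simulate import (SimConfig, plant_duplications, random_genome,
                             simulate_reads)
from remapq.toyalign import ToyAligner
from remapq.io import RunConfig, process_se_group
from remapq.evaluate import sweep_mapq

rng = np.random.default_rng(1)
genome = plant_duplications(random_genome(200_000, rng), rng,
                            n_dups=10, dup_length=2000, identity=0.95)
aligner = ToyAligner(genome, max_edits=8)
cfg = RunConfig()

primaries = []
for read in simulate_reads(genome, 2000, SimConfig(), rng):
    records = aligner.align(read.name, read.sequence, read.qualities)
    ordered = process_se_group(records, cfg)
    if ordered is not None:
        ordered[0].record.mapping_quality = ordered[0].mapq
        primaries.append(ordered[0].record)

print(sweep_mapq(primaries, cutoffs=[0, 10, 20], total=2000))
```

prints

```
   cutoff    TP  FP  FN  precision  sensitivity    FDR
0       0  1998   2   0      0.999       1.0000  0.001
1      10  1995   0   5      1.000       0.9975  0.000
2      20  1995   0   5      1.000       0.9975  0.000
```

i.e. posterior best-hit selection is 99.9% precise on a genome where
~15% of reads are multi-mapped (picking a random candidate instead is
~92% precise), and raising the mapQ cutoff removes the remaining false
placements at a 0.25% sensitivity cost.

The same pipeline is available from the shell:

```bash
remapq sim      --ref ref.fa -n 2000 --out reads.fq --seed 1
remapq toyalign --ref ref.fa --reads reads.fq --out cands.sam --max-edits 8
remapq filter   --in cands.sam --out filtered.sam --mode SE
remapq eval     --sam filtered.sam --out eval.tsv
```

`remapq filter` writes standard SAM/BAM with the recomputed MAPQ plus
diagnostic tags `XL` (log10 likelihood), `XP` (posterior), `XN`
(candidate count), `XM` (mismatches) and `XO` (indels).  Options —
penalties, 1DP, variant VCF, mapQ floor — are documented in `--help`
and can be set from a flat `key=value` config file.  Input must be
name-grouped/name-sorted.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

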