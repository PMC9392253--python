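# mitostructkit

Structural-variation analyses for circular plant mitochondrial genomes
(mitogenomes), built for the kind of questions asked of organelle genomes in
Rosaceae and similar families: how much of the genome is repeated and does
repeat content track genome size; which repeat pairs actively recombine and
how often; how many inversions separate two genome arrangements and how fast
do rearrangements accumulate per million years; which regions show
selective-sweep signatures in wild vs cultivated populations; and which
accessions carry a large deletion, judged from read depth.

Every stage is exercisable end-to-end on synthetic data with known ground
truth, so the whole pipeline is testable without any downloads.

## What it computes

- **Repeat census** (`repeats`): seed-and-extend self-comparison of a
  circular genome on both strands with Karlin–Altschul e-values (defaults:
  word 7, e ≤ 1e-6), repeat pairs classified into the four length classes
  <100, 100–500, 501–1000 and >1000 bp; plastid-derived segments by
  cross-comparison; genome size / repeat-content regression by PGLS under a
  Brownian-motion covariance Var[y] ∝ V with V_ij the shared root-to-tip
  path length.
- **Recombination assay** (`recombination`): for a repeat pair with copies
  *b*, *e* and 200-bp flanks *a,c,d,f*, reference forms *a-b-c*, *d-e-f* and
  recombinant forms {a,d}×{b,e}×{c,f} minus the references (6 forms, or the
  2 forms *a-b-f*, *d-b-c* when *b = e* exactly). A long read supports the
  single form it matches at >99% identity across both flanks; the
  recombination frequency is 100·n_recomb/(n_ref + n_recomb).
- **Rearrangement** (`rearrangement`): exact minimum inversion distance
  between circular signed block orders via Hannenhalli–Pevzner theory
  (d = n+1−c+h+f over the breakpoint graph, after reduction of the circular
  problem to a linear one), blocks from shared unique k-mer anchors, and
  rates in events/Mya — per branch (events/t) or pairwise (events/2T).
- **Population scans** (`popgen`): haploid variant filtering (MAF > 0.01,
  missing < 0.1), sliding-window nucleotide diversity π and Weir–Cockerham
  F_ST (1000-bp windows, 500-bp steps, circular wrap), and sweep calls where
  F_ST > 0.1 and π_wild/π_cul > 2.
- **Deletion genotyping** (`deletion`): presence/absence of a candidate
  region from the depth ratio Idep/Wdep, using the empirical low
  (0.24–0.72) / high (6.94–142.98) bands, carrier frequencies per group with
  Pearson chi-square tests, homologous-sequence totals and an ORF scan
  (ATG→stop, ≥150 bp, both strands).
- **Synthetic data** (`simulate`): circular genomes with planted repeat
  pairs, reads from mixtures of reference and recombinant conformations,
  block orders scrambled by k known inversions, two-population haplotype
  matrices with planted sweeps, and band-generated depth ratios — all
  deterministic under a seed.

## Worked example

```python
from mitostructkit.simulate import SimulationConfig, gen_circular_genome, sim_long_reads
from mitostructkit.repeats import find_repeats, repeats_to_frame
from mitostructkit.recombination import (
    build_recombinant_references, assign_reads, recombination_frequency,
)

cfg = SimulationConfig(seed=1, genome_length=20_000,
                       repeat_spec=((2000, 100.0, 1),),   # one exact 2-kb pair
                       recomb_fraction=0.3, coverage=60,
                       read_length_mean=3000, read_length_sd=800)
genome, truth = gen_circular_genome(cfg)
pairs = find_repeats(genome)
print(repeats_to_frame(pairs).to_string(index=False))
reads = sim_long_reads(genome, truth[0], cfg)
assay = assign_reads(reads, build_recombinant_references(genome, pairs[0]))
print(f"n_ref={assay.n_ref} n_recomb={assay.n_recomb} "
      f"frequency={recombination_frequency(assay):.2f}%")
```

prints

```
 startA  endA strandA  startB  endB strandB  length  identity class orientation
  11046 13046       +   18000 20000       +    2000     100.0 >1000      direct
n_ref=15 n_recomb=6 frequency=28.57%
```

The caller recovers the planted 2-kb pair at its exact coordinates; of the
400 simulated reads, 21 span a junction with both 200-bp flanks at >99%
identity, and the fraction supporting a recombinant arrangement (28.57%)
estimates the planted mixture fraction of 30% to within binomial noise.

A command-line interface mirrors the stages:

```bash
mitostructkit repeats --genome genome.fasta --min-word 7 --evalue 1e-6
mitostructkit all --config run.yaml --outdir out/   # full pipeline + manifest
```

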