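# introscan

Windowed population-genomic scans for detecting and localizing
introgression in crop resequencing cohorts, built around the analyses used
to dissect the breeding history of hexaploid oat: hulled oat (*Avena
sativa*), naked oat landraces and cultivars, and closely related hexaploid
outgroups. The package is aimed at researchers analyzing biallelic-SNP
panels from selfing crop cohorts who want the standard scan battery as a
tested, scriptable library rather than a chain of one-off tool
invocations.

## What it computes

- **Site filtering** — genotype calls with GQ < 10 are masked to missing,
  then sites are removed when QUAL < 30, INFO/FS > 60, INFO/MQ < 40, the
  fraction of passing calls < 0.8, MAF < 0.05 or missing rate > 20%
  (removal clauses are strict, so boundary values survive). Ts/Tv is
  reported as a call-quality check.
- **Diversity and differentiation** — nucleotide diversity per window,
  π = Σ_sites 2c(n−c)/(n(n−1)) / window bp, in 1 Mb windows with 500 kb
  steps; Weir–Cockerham (1984) F<sub>ST</sub> = Σa / Σ(a+b+c) (ratio of
  sums); pairwise IBS distance; diversity over repeated fixed-size
  subsamples to remove sample-size effects.
- **Runs of homozygosity** — the PLINK sliding-window heuristic
  (50-SNP windows, ≤ 2 missing, 0 heterozygous; runs kept at ≥ 50 SNPs,
  ≥ 500 kb, ≤ 50 kb/SNP).
- **LD decay** — mean genotype r² of SNP pairs within 1 Mb, binned by
  distance.
- **Patterson's D (ABBA–BABA)** — frequency-weighted
  D = Σ(ABBA−BABA)/Σ(ABBA+BABA) with derived alleles polarized by the
  outgroup and a weighted delete-one block jackknife (Busing et al. 1999)
  over physical blocks for the z-score.
- **rIBD introgression scan** — per 100 kb/50 kb window, counts of IBD
  segments shared between a target population and each of two candidate
  donor populations, normalized by donor panel size:
  rIBD = nIBD_OH − nIBD_ONL, z-standardized genome-wide; windows with
  z > 2 merge into putative introgressed segments, with gene overlap and
  per-subgenome length accounting.
- **Divergence dating** — fourfold-degenerate third positions extracted
  from GFF3 gene models, a strict QUAL ≥ 60 / GQ ≥ 30 genotype filter, and
  a strict-clock calibration ratio t = t_calib · d_target/d_calib
  (calibration outgroup split 0.78 Mya by default).
- **Candidate-gene haplotypes** — samples grouped by exact genotype
  identity over a gene ± 2 kb upstream (strand-aware), with Welch t-tests
  between group phenotypes.
- **Synthetic cohorts** — a founder-mosaic simulator generates cohorts
  with known ancestry tracts, true IBD segments, genotype-call noise
  (QUAL/FS/MQ/GQ), a planted admixture pulse, and a planted causal
  haplotype effect, so every scan is testable end to end without any
  external data.

## Worked example

Simulate a 20 Mb cohort (12 hulled, 20 naked-landrace, 8 cultivar, 4
outgroup diploids) with a 10% introgression pulse from the hulled pool
into the cultivars, then run the scan battery:

```python
import numpy as np
from introscan import simpop, variantio, diversity, introgression

cfg = simpop.SimConfig(seq_length=20_000_000, n_oh=12, n_onl=20, n_onc=8,
                       n_og=4, admix_fraction=0.1, seed=1)
table, truth = simpop.simulate_cohort(cfg)
pop = lambda l: [s for s, p in truth.populations.items() if p == l]

masked = variantio.mask_low_gq(table, 10)
kept, _ = variantio.filter_sites(masked)

windows = diversity.make_windows({"chr1": cfg.seq_length})
pi = diversity.nucleotide_diversity(kept, pop("ONL"), windows)

d = introgression.patterson_d(kept, pop("ONL"), pop("ONC"), pop("OH"),
                              pop("OG"), block_size=2_000_000)

scan = diversity.make_windows({"chr1": cfg.seq_length}, 100_000, 50_000)
rw = introgression.ribd_scan(truth.true_ibd, pop("ONC"), pop("OH"),
                             pop("ONL"), scan)
segs, total, frac = introgression.call_introgressed_segments(
    rw, 2.0, {"chr1": cfg.seq_length})
```

Output:

```text
sites kept after filtering: 215673/316051
Ts/Tv: 2.01
mean window pi (ONL): 3.51e-04
Patterson's D = 0.913, z = 10.6 (10 blocks)
introgressed segments: 1, total 1.75 Mb (8.8% of genome)
planted donor total: 2.00 Mb
```

Reading the numbers: the filter keeps about two-thirds of raw sites and
the Ts/Tv of ~2 matches the simulator's configured transition bias, as in
a clean SNP set. D is strongly positive with |z| ≫ 3, the signature of
excess derived-allele sharing between the cultivars (p2) and the hulled
pool (p3) — under the founder-mosaic model, which has no incomplete
lineage sorting, D magnitudes are much larger than in real data and only
the sign and z matter. The rIBD z > 2 windows merge into one segment that
recovers the planted 2 Mb donor pulse to within one window step.

The same operations are exposed as `introscan` subcommands
(`simulate`, `filter`, `pi`, `fst`, `ibs`, `subsample-pi`, `ld`, `roh`,
`haplogroup`, `dstat`, `ribd`, `fourfold`, `divtime`); see
`introscan --help`.

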