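# Methods

## The analysis problem

Given a biallelic-SNP panel for a structured crop cohort — here a
hulled-oat population (OH), naked-oat landraces (ONL), naked-oat cultivars
(ONC) and hexaploid outgroup relatives (OG) — the pipeline asks three
questions: how is diversity apportioned within and between the groups
(π, F<sub>ST</sub>, IBS, ROH, LD decay); is there genome-wide evidence of
gene flow into the cultivars (Patterson's D); and where in the genome do
the introgressed segments lie (the rIBD scan), with calibrated dating of
the deeper population split (fourfold-site clock) and phenotype contrasts
at candidate regions.

## Site filtering

Genotype calls with GQ below 10 are masked to missing before any site
statistic is computed. A site then survives iff QUAL ≥ 30, FS ≤ 60,
MQ ≥ 40, the fraction of samples with a called genotype at GQ ≥ 10 is at
least 0.8, MAF ≥ 0.05 and missing rate ≤ 0.20. Removal clauses are strict
inequalities, so boundary values survive. MAF and missing rate are
computed after masking. Sites lacking an FS or MQ annotation pass those
clauses: annotation absence is not evidence of failure. The filter is
idempotent and is checked in the tests against an independent per-site
boolean re-evaluation.

## Estimators

**π.** Per site with n called alleles and derived count c, the unbiased
pairwise estimator 2c(n−c)/(n(n−1)). Window values divide the sum over
variant sites by the *full window length* in bp (monomorphic positions are
zero-diversity sites), the convention of windowed-π tools, which puts
values on the ~10⁻³–10⁻⁴ scale familiar from crop panels. Truncated
terminal windows use their true length. Group-level summaries are the
mean over 1 Mb / 500 kb sliding windows.

**F<sub>ST</sub>.** Weir & Cockerham (1984) variance components a (among
populations), b, c per site, with observed heterozygote frequencies (not
HWE expectations) — important in selfing crops where hets are rare. Window
values are ratio-of-sums Σa/Σ(a+b+c) ("weighted" F<sub>ST</sub>); negative
windows are reported as computed. A fixed difference between equal-sized
samples gives exactly 1.

**IBS distance.** 1 − mean per-site similarity (1 − |gᵢ−gⱼ|/2) over sites
co-called in both samples; pairs with zero co-called sites get NaN.

**ROH.** The PLINK scanning heuristic, transcribed: 50-SNP windows are
"permissible" with ≤ 2 missing and 0 heterozygous calls; each SNP's hit
rate is the permissible fraction of windows covering it; SNPs with hit
rate ≥ 0.05 and a non-heterozygous call are run-eligible; maximal eligible
runs split at > 1,000 kb gaps and are kept at ≥ 50 SNPs, ≥ 500 kb and
≤ 50 kb/SNP. The two unprinted knobs (hit threshold, max gap) are the
PLINK defaults. The implementation is vectorized; the test suite carries a
separate loop-by-loop transcription of the rules and requires exact
agreement on random instances.

**LD decay.** Genotype r² — the squared Pearson correlation of diploid
dosage vectors over samples co-called at both sites — for all
same-chromosome pairs within 1 Mb, averaged in 500 bp distance bins (bin
width configurable; coarser bins are used on desk-scale cohorts). Pairs
with fewer than 4 co-called samples or zero dosage variance are skipped.
Genotype r² needs no phasing and is invariant to allele relabeling.

**Patterson's D.** Population derived-allele frequencies p̂₁…p̂₄ per site,
with polarization by the outgroup: the allele minor in the outgroup is
derived; sites with outgroup derived frequency in (0.1, 0.9) are dropped
as unpolarizable. ABBA = (1−p̂₁)p̂₂p̂₃(1−p̂₄), BABA = p̂₁(1−p̂₂)p̂₃(1−p̂₄),
D = Σ(ABBA−BABA)/Σ(ABBA+BABA). The standard error is a weighted
delete-one block jackknife (Busing, Meijer & van der Leeden 1999) over
contiguous *physical* blocks (5 Mb by default; no genetic map is assumed),
with block weights proportional to the block's ABBA+BABA mass; z = D/SE.
D > 0 means excess p2–p3 sharing. The tree orientation (which population
is p1/p2/p3) is caller-specified; for the oat question the documented
default is p1 = naked landraces, p2 = naked cultivars, p3 = hulled,
outgroup = hexaploid relatives, under which introgression from hulled oat
into the cultivars drives D positive.

**rIBD.** For each 100 kb window (50 kb step), c(w) counts IBD segments
with one endpoint in the target population and one in the reference
population that overlap the window by ≥ 1 bp (the overlap rule is
configurable to midpoint containment); nIBD = c/|reference panel|;
rIBD = nIBD_OH − nIBD_ONL. Counting is pooled over all target samples —
any per-cultivar averaging constant cancels under the genome-wide
z-normalization, which is applied over *all* windows (zero-IBD windows
included). Windows with z strictly above 2 merge by interval union into
putative introgressed segments; total length, genome fraction, overlapping
genes (≥ 1 bp rule against the gene span) and per-subgenome totals are
reported. IBD input is a RefinedIBD-style 8-column TSV (1-based inclusive
in the file, converted to 0-based half-open internally); IBD *detection*
is out of scope — the simulator provides exact truth-derived IBD instead.

**Fourfold sites and the clock.** The eight fourfold codon families are
derived from the standard genetic code at import (and checked in tests
against a hand-enumerated list). For each translatable transcript (CDS
length a multiple of 3 after phase trimming), every codon whose first two
bases fix the amino acid contributes its third position, mapped to genomic
coordinates strand-aware; positions claimed as fourfold by one transcript
but covered in any other role by another are excluded rather than voted
on. Genotypes at those sites pass a strict filter — QUAL ≥ 60 and every
accession called with GQ ≥ 30 — and distances between two diploids are the
mean over the 2×2 haploid comparisons per site, averaged over *all*
retained fourfold sites (absent sites are invariant, i.e. zero
difference): divergence is per fourfold site, not per variant site, as a
clock calibration requires. The split time is the strict-clock ratio
t = t_calib · d_target/d_calib with d_calib the mean of the two
focal-versus-outgroup distances and t_calib = 780,000 years by default
(1-year generations). This estimator deliberately replaces Bayesian
relaxed-clock dating: it is exact under a strict clock, scale-invariant in
the distances, and testable by parameter recovery at desk scale. It cannot
express rate heterogeneity between lineages.

**Haplotype contrast.** Samples with complete genotypes over a region
(gene span + 2 kb strand-aware upstream flank) are partitioned by exact
genotype-vector identity; groups of ≥ 3 are ranked by size (Hap.1
largest). Group phenotypes are compared by Welch's unequal-variance
t-test (a flag restores the pooled-variance Student form) at α = 0.01,
with a compact-letter display for plots. Genotype identity, not phased
haplotype identity, defines groups — appropriate for heavily selfing
cohorts where most accessions are homozygous across candidate regions.

## The synthetic cohort generator

A founder-mosaic model, not a coalescent. Each population has K founder
haplotypes (default 10). Mutations are placed under infinite sites on a
fixed tree: an outgroup stem, an ingroup stem, population stems, and one
branch of length t_within per founder, with counts Poisson(μ·L·t) per
branch; so within-population divergence between distinct founders is
2μ·t_within, OH–ONL divergence is 2μ·t_split, and outgroup divergence is
2μ·t_og — closed forms the tests verify by direct Hamming counts. Each
sample haplotype is a recombinant mosaic of its population's founders with
Poisson(r·L·admix_age) uniform crossovers; with probability `selfing`
(default 0.7, a selfing crop) a sample's second haplotype is a copy of its
first, which produces realistic ROH and mostly-homozygous candidate
regions.

The cultivar admixture pulse is *planted*: donor intervals from the OH
founder pool totalling exactly round(f·L) bp, with exponential-ish lengths
at the recombination tract scale (mean 1/(r·admix_age) ≈ 2.2 Mb at the
defaults) and uniform non-overlapping placement, each carrying one OH
founder. A small pool of admixed cultivar founders (default 4) shares
these intervals over independent ONL-founder backbones, and cultivar
haplotypes are mosaics of that pool. This emulates introgressed segments
that entered the cultivar gene pool through a few historical crosses and
are therefore *common* to the cultivars — the situation an rIBD scan is
designed to detect — and makes the realized donor fraction equal f by
construction. Degenerate settings behave sensibly: f = 0 gives no donor
ancestry, f = 1 makes cultivars indistinguishable from the hulled pool in
mean pairwise distance.

Genotype noise: each haploid allele flips with probability
`error_rate` = 5·10⁻⁴; calls containing a flipped allele draw GQ from a
low-mean exponential (mean 4) while correct calls draw from N(60, 12²), so
the GQ < 10 mask removes ~92% of errors. The residual heterozygous error
rate (~8·10⁻⁵ per call) leaves long ROH intact — with one spurious het per
several hundred kb in a selfed sample, ≥ 500 kb runs survive the
zero-het window rule. Site annotations (integer-valued QUAL, FS, MQ, so
the VCF round-trips bit-exactly through htslib's float32 QUAL) include
small planted fractions of filter-failing sites. Mutations choose a
transition with probability κ/(κ+1) (κ = 2 by default), so the expected
Ts/Tv *count ratio* equals κ ≈ 2, the value a clean SNP set shows.

True IBD is derived exactly: maximal intervals ≥ 100 kb where two
haplotypes carry the same founder, with lod set to the length in kb. The
causal phenotype model picks the highest-MAF site (ties broken nearest the
chromosome middle) and sets phenotype = baseline + effect × allele copies
+ N(0, σ); effect defaults to 2σ.

**What the simulator does not emulate, and what that means for the
tests.** There is no incomplete lineage sorting (founder trees are stars
within populations), so the BABA class is nearly empty and D magnitudes
under gene flow approach 1 rather than the ~0.02 seen in deep real
panels; the tests therefore assert null calibration and planted sign, not
D magnitude. There is no recurrent mutation, no gene conversion, no
hexaploid homoeology or subgenome structure (single chromosome), no
background selection, and within-population coalescence cannot predate
the population split, which caps attainable π relative to F<sub>ST</sub>.
Passing tests demonstrate that the estimators compute their definitions
correctly and recover planted signals under calibrated noise — not that
the demographic model is realistic.

## Study-condition defaults and numerical choices

- μ = 6.5·10⁻⁹ per site per generation, 1-year generations; t_split =
  51,200; t_og = 780,000 (the calibration depth); t_within = 45,000
  (bounded above by t_split in a star model); r = 10⁻⁸/bp; admix_age = 45,
  giving ~2.2 Mb donor tracts; f = 0.1; cohort 22/81/8/4 diploids.
- Test and acceptance runs scale the genome to 0.3–20 Mb and samples to
  tens of diploids; the D-statistic calibration study uses a 10 Mb genome
  (~150k segregating sites), an older pulse (admix_age = 500, so the 10%
  donor mass spreads over ~5 tracts) and 500 kb jackknife blocks, because
  a single 2 Mb donor tract concentrates all signal in one block and the
  delete-one jackknife then correctly reports high uncertainty.
- Internal coordinates are 0-based half-open everywhere; VCF stays 1-based
  at the boundary; BED output is 0-based. IBD TSVs are 1-based inclusive.
- Windows are generated per chromosome as [k·step, k·step+size) while the
  start is inside the chromosome, final window truncated.
- rIBD requires non-constant window values (sd > 0) and errors out on
  degenerate input rather than emitting all-zero z-scores.
- Ties in haplotype-group ordering break on the genotype vector; all
  writers sort output deterministically; every stochastic routine takes an
  explicit seed and the CLI is byte-reproducible for fixed seeds.

## Known limitations

- The divergence clock assumes rate constancy; between-lineage rate
  variation biases t linearly and is not modeled.
- The cohort-wide MAF ≥ 0.05 filter strips variation private to small
  populations (visible as depressed π in the smallest group of a cohort) —
  a property of the filter itself, reproduced faithfully.
- IBS distances and LD loops are quadratic in samples/sites and are meant
  for cohort-scale (hundreds of samples), not biobank-scale, inputs.
- The rIBD scan consumes externally detected (or truth-derived) IBD; it
  inherits whatever detection biases its input carries.
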