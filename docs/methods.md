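# Methods

## Model

The pipeline analyses pooled sequencing of two phenotypic bulks from an
F2 of a homozygous recessive mutant crossed to a wildtype cultivar.

**Pool genetics.** Each of a bulk's 2N chromosomes either carries the
causal mutant allele or not. A chromosome carrying it also carries the
linked marker allele with probability 1 − r, a non-carrier with
probability r, so the expected marker-allele frequency is affine in r
(`genetics.expected_bulk_freq`): f(r) = f0(1 − r) + (1 − f0)r with
f0 = (2·n_MM + n_Mm)/2N. Consequences used throughout: a mutant bulk of
17 homozygotes + 1 heterozygote has f0 = 35/36 (97 % to whole percent);
an ideal wildtype bulk (hets : homozygous wildtypes = 2:1 among
phenotypic wildtypes of a recessive trait) has f0 = 1/3; every bulk sits
at 1/2 at unlinked loci.

**Map functions.** Haldane, r = (1 − e^(−2d))/2 (d in Morgan), is the
process model: it corresponds exactly to the simulator's
interference-free, interval-wise Bernoulli crossovers. Kosambi,
r = tanh(2d)/2, is provided because linkage maps in this field are
usually reported in Kosambi cM; it is never used to generate data.

**Segregation test.** Pearson goodness of fit on two phenotype classes,
df = 1, no continuity correction, p from the upper χ²(1) tail. The
uncorrected statistic is the one that reproduces the reference value for
19:81 against 3:1 (χ² = 1.92, p = 0.166, displayed to 3 significant
figures); Yates' correction would give ≈1.61.

## Stage 1 — allele-frequency mapping

Per-site pool frequency is alt/(ref+alt) from the VCF AD field (never
the site DP, so the definition is exactly "reads supporting the allele
over reads at the site"). Filters, in order:

1. total depth ≥ 30 in **both** pools (default `min_depth=30`);
2. sites with frequency ≥ 0.80 in **both** pools removed (uninformative
   divergence between the mutant's genetic background and the reference;
   the causal signature — high in the mutant pool only — passes);
3. sites on unanchored contigs excluded from binning (counted, logged).

Surviving sites inherit their contig's (chromosome, cM) anchor and are
averaged, unweighted, in half-open bins [k·w, (k+1)·w) of width
w = 1 cM; bins with fewer than 30 SNPs are dropped. The peak is the bin
maximizing score = f_mut − f_wt, ties broken by chromosome order then
lower bin start; a best score below 0.2 logs a no-signal warning. The
score's two-pool contrast makes it robust to genome-wide reference
divergence, and it is maximal in expectation at the causal locus.

## Stage 2 — deletion scan

Intervals are maximal runs of consecutive positions with wildtype depth
> 0 — runs are defined on the wildtype track so a fully deleted mutant
region still yields an interval — clipped to each capture target they
overlap by ≥ 1 bp. Per-pool means are taken over every base of the
clipped interval (absent positions count 0). Zero-coverage gaps are not
bridged (gap tolerance 0): a single uncovered base splits a run. Calls,
for intervals ≥ 150 bp (inclusive):

* condition 1: wildtype mean ≥ 5× and mutant mean = 0;
* condition 2: mutant mean ≤ 2×, wildtype mean ≥ 5× and
  wildtype ≥ 4 × mutant (checked after condition 1).

The ratio is implemented multiplicatively (wt ≥ ratio·mut) so it is
well-defined at mutant mean 0, and in the wildtype/mutant direction —
the only direction satisfiable alongside the ≤2×/≥5× bounds. Condition 2
exists because one mis-phenotyped heterozygote in an 18-plant mutant
bulk leaves 1/36 of the chromosomes intact, hence a thin residue of
coverage over a homozygous deletion. Means are reported to one decimal;
calls use full precision.

## Stage 3 — candidate ranking

Calls are partitioned by anchor-table membership; anchored calls on the
focal chromosome within a closed cM interval (explicit bounds, or peak
bin midpoint ± 15 cM by default — the bin midpoint because bins are the
analysis resolution) are joined to gene models by ≥ 1 bp overlap on the
same contig. One candidate per gene, sorted by distance to the peak
(ascending), longest deleted interval (descending), high before low
confidence, gene id. Calls overlapping no gene are reported separately
rather than dropped.

## Synthetic data

The generator reproduces the study design: 100 F2 individuals from two
independent gametes each; gametes built marker-to-marker with Haldane
recombination probabilities on inter-marker distances (equivalent to a
Poisson crossover process without interference); recessive phenotype on
the causal dosage. Bulks: 18 plants of which one is a mis-phenotyped
heterozygote, and 30 drawn uniformly from the phenotypic wildtypes.

Default map: 2 chromosomes × 150 cM, 150 evenly spaced contigs per
chromosome (one per cM), 35 markers per contig all at the contig's
anchor position (kb-scale contigs recombine negligibly within
themselves), 5 % of contigs unanchored, causal locus at (1H, 97 cM) on
an always-anchored contig. Each contig also carries one gene and two
capture targets at fixed template coordinates; on the causal contig the
two targets are the causal gene's exons and are homozygously deleted in
dosage-2 individuals (the deletion *is* the causal mutation, so it
co-segregates perfectly and doubles as the causal SNP marker).

Sequencing model, two instances with different depths:

* **SNP sites**: depth ~ negative binomial, mean 60×, dispersion 20
  (Poisson optional); alternate reads ~ Binomial(depth, f(1−e) + (1−f)e)
  with per-read error e = 0.002. The mean must sit well above the 30×
  filter: at mean 30 only ~25 % of sites would pass "≥30× in both
  pools" and every bin would fall under the 30-SNP rule; 60× leaves
  ~95 % of sites and keeps the deep-capture regime of the real
  experiment.
* **Capture-target tracks**: per-base Poisson around mean 25× times a
  per-target lognormal capture-efficiency factor (σ = 0.5) shared by
  both pools — target-level efficiency variation is what keeps the
  deletion screen from being trivially clean. 25× matches the per-target
  pool means observed in real capture data (roughly 7–25×) and keeps the
  heterozygote's residual (25/36 ≈ 0.7× times the factor) below the 2×
  call threshold except for extreme factors. On deleted exons the
  Poisson mean scales with the fraction of non-deleted chromosomes in
  the bulk (1/36 for the 17+1 mutant bulk, ~2/3 for the wildtype bulk).

All randomness flows from one seed through spawned substreams (meioses,
bulk draw, read sampling, capture factors); a fixed seed gives
byte-identical output files. When a seed segregates too few phenotypic
mutants to fill the bulk (P ≈ 3 % at n = 100), the meioses are re-drawn
from a derived sub-seed — the in-silico analogue of only running the
experiment on a usable population; this conditions the Mendelian ratio
slightly upward in the selected populations.

**What the generator does not emulate:** read-level artifacts (mapping
bias, paralogy, duplicates), indels and multi-allelic sites, linkage of
background polymorphism to phenotyping errors, contig mis-anchoring, and
capture-probe edge effects within targets. Passing tests therefore show
the *statistical* machinery is correct under the stated design, not that
the pipeline is robust to assembly or alignment pathology.

## Intrinsic mapping resolution

With bulks of 18 (+1 het) and 30 from 100 plants, the true score surface
drifts between loci with sd ≈ 0.09 (bulk-sampling variance of the
chromosome draw), and a recombination of the contaminant heterozygote's
wildtype chromosome a few cM from the causal locus makes the mutant bulk
locally *pure* (f = 36/36 > 35/36). In roughly a quarter of simulated
replicates a bin 3–7 cM away therefore genuinely outscores the causal
bin. The experiment's localization accuracy is thus a few cM — entirely
sufficient to shortlist gene-bearing contigs in a 30-cM interval, which
is the procedure's actual use — and the peak-bin mutant frequency is
≈0.97 when the peak lands on the causal bin and slightly lower a few
bins away. Simulated checks of peak location use this realistic spread;
candidate ranking is insensitive to it (the causal gene ranks first in
all tested seeds) because ranking only needs the peak as a focal point,
not to the bin.

Null calibration: with phenotype-blind bulks of the same sizes the
maximum |score| over ~300 bins lies between 0.20 and 0.35 in every
tested seed — bulk-sampling drift alone reaches the 0.2 warn threshold,
so the threshold should be read as "no *strong* signal", and a causal
locus (score ≈ 0.6) remains clearly separated from the null.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; BED converts at the
  boundary (a BED line `ctg 2106 2455` is 2107..2455, length 349).
* "Mutant allele" ≡ VCF alternate allele, assuming reads were aligned to
  the wildtype outcross parent's assembly; `--mutant-is-ref` flips
  polarity when the reference is the mutant-background cultivar.
* The ≥80 % filter uses ≥ (not >), applied after the depth filter.
* Depth files with fewer columns than declared samples are a hard error,
  never a silent zero-fill; depth positions must be strictly increasing
  per contig; absent positions mean depth 0.
* The mapping interval around the peak defaults to ±15 cM; closed bounds
  on both sides (a contig exactly on the boundary is inside).
* p-values display to 3 significant figures; test comparisons use 5e-3.
* Bulk sizes, filters and thresholds are all exposed as flags/arguments;
  defaults are the published procedure's values.

## Problem sizes used in tests and the acceptance script

The shipped scenario (2 × 150 cM, 35 SNPs/cM ≈ 10,500 markers, 100
plants) simulates in ~0.2 s, so the test suite runs replicate sets (10
ranking seeds, 20 peak seeds, 500 random deletion-scan tracks ≤ 5 kb,
10,000 gametes for recombination checks) in well under a minute; the
acceptance script's 20 replicates finish in a few seconds.

## Known limitations

* Biallelic SNPs only; multi-allelic records and indels are skipped.
* No CNV segmentation, split-read or paired-end evidence — the deletion
  screen is exactly the two-condition coverage rule, aimed at large
  radiation-induced deletions (≥150 bp).
* No confidence envelope on the peak (no simulation bands); peak
  reporting follows the visual-inspection procedure it formalizes.
* Genome-scale anchoring splits (hundreds of calls across a real
  genome) are exercised by the logging contract, not reproduced at desk
  scale.
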