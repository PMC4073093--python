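# bulkmap

Bulked-segregant mapping-by-sequencing for species with fragmented,
genetically anchored draft assemblies — written with barley-scale forward
genetics in mind, but applicable to any selfing crop with a contig-level
assembly and a cM anchor table.

## The problem

A recessive mutant is outcrossed to a wildtype cultivar and the F1 is
selfed to give an F2 population. DNA from a bulk of phenotypic mutants and
a bulk of wildtypes is pooled, enriched by exome capture, and sequenced.
Because every phenotypic mutant is homozygous at the causal locus, the
mutant pool's alternate-allele frequency approaches 1 at markers linked to
it, while the wildtype pool (hets : homozygous wildtypes = 2 : 1) stays
near 1/3. Without a contiguous reference genome, sites cannot be ordered
along chromosomes directly; instead each assembly contig carries a genetic
anchor (chromosome, cM), and frequencies are averaged in cM bins.

For radiation-induced mutants the causal lesion is often a large deletion,
so a second, orthogonal screen looks for capture targets that are covered
in the wildtype pool but (almost) devoid of reads in the mutant pool.

`bulkmap` implements the three analysis stages plus a ground-truth
simulator:

| module | what it does |
|---|---|
| `allele_frequency` | per-site pool frequencies → ≥30× filter → 1-cM bin means → peak call |
| `deletion_scan` | per-base depth → contiguously covered intervals over capture targets → two-condition deletion calls |
| `candidate_ranking` | anchor calls on the genetic map, restrict to the mapping interval, join genes, rank by distance to the peak |
| `synthetic_data` | simulate the whole experiment (meioses → bulks → pooled counts and depth tracks) with known truth |
| `genetics` | map functions (Haldane/Kosambi), expected pool frequencies, segregation χ² |
| `io_formats` | depth tracks, two-sample VCF (AD), BED targets, anchor and gene tables |

## The model in brief

For a bulk whose causal-locus composition is (n_MM, n_Mm, n_mm) plants,
the expected frequency of the mutant-linked allele at a marker with
recombination fraction *r* is affine in *r*:

    f(r) = f0 (1 − r) + (1 − f0) r,   f0 = (2 n_MM + n_Mm) / 2N

so a mutant bulk of 17 homozygotes plus one mis-phenotyped heterozygote
peaks at f0 = 35/36 ≈ 97 %, not 100 % — and the same lone heterozygote
leaves a thin residue of reads over a homozygous deletion, which is why
the deletion screen has a relaxed second condition (mutant mean ≤ 2×,
wildtype ≥ 5× and ≥ 4-fold higher) besides the strict one (mutant = 0,
wildtype ≥ 5×), both applied to contiguously covered intervals ≥ 150 bp.
Distances convert to recombination fractions via Haldane
(r = (1 − e^(−2d))/2, no interference; the simulator's process model) or
Kosambi (r = tanh(2d)/2, for reporting).

## Worked example

The shipped example dataset (`bulkmap.examples`) holds the eight deleted
capture-target intervals found on barley chromosome 5H in the *many-noded
dwarf* (*mnd*) experiment, with per-pool mean depths and contig anchors:

```python
from bulkmap import deletion_scan as ds, candidate_ranking as cr, examples
from bulkmap.genetics import BulkComposition, expected_bulk_freq, segregation_chi2

res = segregation_chi2(19, 81, expected_mutant_fraction=0.25)
print(f"chi2 = {res.chi2:.2f}, p = {res.p_value:.3f}")

f = expected_bulk_freq(0.0, BulkComposition(n_hom_mutant=17, n_het=1, n_hom_wildtype=0))
print(f"expected mutant-bulk peak frequency = {f:.4f} ({100*f:.0f}%)")

calls = ds.call_deletions(examples.mnd_intervals())
anchored, _ = cr.anchor_deletions(calls, examples.mnd_anchors())
in_iv = cr.select_in_interval(anchored, "5H", 80.0, 110.0)
ranked = cr.rank_candidates(in_iv, examples.mnd_genes(), focal_cm=97.0)
print(cr.candidates_to_frame(ranked).head(3).to_string(index=False))
```

prints

```
chi2 = 1.92, p = 0.166
expected mutant-bulk peak frequency = 0.9722 (97%)
     gene_id         contig confidence         annotation    cm  n_intervals  deleted_bp  longest_bp  dist_to_peak_cm
MLOC_64838.2   contig_49382       high    Cytochrome P450  96.6            2         580         349              0.4
MLOC_10070.1 contig_1558349       high MATE efflux family  99.9            1         242         242              2.9
MLOC_21734.1  contig_159829       high         CC-NBS-LRR  99.9            2         421         212              2.9
```

The 19 : 81 segregation is consistent with a monogenic recessive trait
(χ² = 1.92, p = 0.17); all eight intervals are called as deletions; six
distinct genes remain after joining, and the cytochrome P450 gene whose
two exons are deleted ranks first — 0.4 cM from the allele-frequency
peak, carrying the longest deleted interval (349 bp).

## Command line

```
bulkmap simulate --outdir sim --seed 1        # synthetic experiment + truth.json
bulkmap freqmap  --vcf sim/pools.vcf --anchors sim/anchors.tsv --out freq.tsv
bulkmap delscan  --depth sim/depth.tsv --targets sim/targets.bed --out calls.tsv
bulkmap rank     --calls calls.tsv --anchors sim/anchors.tsv \
                 --genes sim/genes.tsv --freqmap-tsv freq.tsv --out ranked.tsv
bulkmap run      --vcf ... --depth ... --targets ... --anchors ... --genes ... --outdir out
bulkmap stats    --segregation 19,81 --map-cm 10 --bulk 17,1,0
```

Every threshold defaults to the published procedure (≥30× in both pools,
≥80 %-in-both exclusion, 1-cM bins with ≥30 SNPs, ≥150 bp intervals, 5× /
≤2× / ratio 4) and can be overridden by flags; `run` also reads a flat
`key=value` config file and writes a JSON summary with counts at every
filter boundary.

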