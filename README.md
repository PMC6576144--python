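# canyonpool

Pooled-sequencing population genomics for **two-slope cohort contrasts**:
a reusable pipeline for studies that compare pooled isofemale *Drosophila*
lines sampled from two microclimatically opposed habitats (a mesic
north-facing slope, **NFS**, versus a xeric south-facing slope, **SFS**, as
in the Evolution Canyon system). From per-line pooled SNP tables it
computes diversity and differentiation statistics, detects selective
sweeps per line with a hidden Markov model, scores genes by how
asymmetrically they are swept between slopes, quantifies transspecies
(shared) polymorphism with a second species, and analyses
transposable-element (TE) insertion divergence.

Because the original raw data live in a sequence archive, the package
ships a **synthetic two-slope cohort generator** with known ground truth
(planted sweep intervals, true slope frequencies, TE carrier sets, a
cross-species site map) so that every stage is testable end to end.

## What it computes

For pools of *n* haplotypes with per-site alternate read frequency
p̂ = alt/(alt+ref), per 5-kb window and per gene:

- **Heterozygosity** — mean per-SNP 2p̂(1−p̂)·n/(n−1);
- **Watterson's θ** — S/(a_n·L) with a_n = Σ_{i=1}^{n−1} 1/i;
- **Tajima's D** — (π − S/a₁)/√(e₁S + e₂S(S−1)) with the classical
  constants; negative D indicates the rare-variant excess left by a sweep;
- **F_ST** per SNP — (H_T − H̄_S)/H_T from the two slope-level frequencies;
- **Sweep regions** per line — a 3-state HMM (Neutral / Intermediate /
  Selection) whose states are site-frequency spectra over derived-allele
  counts 1..n−1; emissions integrate binomial read sampling over the
  spectrum, transitions use a per-site switch probability k = 1e-10, and
  Viterbi runs of the Selection state become regions;
- **Differential sweep score** per gene — N − S, the number of NFS lines
  whose sweep regions overlap the gene minus the SFS count (range −9..9
  for a 9+9 design; |score| ≥ 6 marks slope-prevalent genes);
- **Transspecies polymorphism** — sites polymorphic for the same allele
  pair in both species: major-allele co-occurrence enrichment,
  cross-species correlation of interslope frequency differences, and the
  filter for nonsynonymous, slope-divergent, slope-concordant SNPs;
- **TE divergence** — per-family sharing percentages, Fisher exact tests
  of copy number and sharing, 100-kb density tracks, CDS-disruption
  tables, and per-site carrier-count divergence scores.

## Worked example

```python
from canyonpool import SimulationConfig, simulate_cohort, pipeline

cohort = simulate_cohort(SimulationConfig(seed=11))   # 1 Mb, 9+9 lines, 73x
results = pipeline.analyze_cohort(cohort)
print(results["chromosome_summary"].round(3).to_string(index=False))
```

prints

```
chrom  tajima_d_nfs  tajima_d_sfs  het_nfs  het_sfs   fst
   2R        -0.015        -0.536    0.234    0.198 0.172
```

The default configuration plants two sweeps on the SFS side only, so the
SFS pool shows depressed Tajima's D and heterozygosity while NFS stays
neutral, and the calibrated interslope F_ST sits at 0.17. Downstream:

```
planted sweep recall: 1.00  FDR: 0.00
SFS-prevalent genes (score <= -6): 20
Spearman r(score, D_NFS - D_SFS) = -0.693 (p = 1.39e-15)
transspecies sites: 408; major-allele co-occurrence fold = 2.34
P-element sharing: 7%  INE-1 sharing: 90%
```

All 20 genes inside the planted intervals are recovered as SFS-prevalent;
the score is strongly anticorrelated with the interslope Tajima's D
difference (genes swept on one slope lose diversity there); fewer than 1%
of polymorphic sites are shared with the second species, with major
alleles co-occurring ~2.3-fold more often than independent assignment
predicts; and the recently invading P-element-like family is far less
shared between slopes than the old, nearly fixed INE-1-like family.

A command-line interface mirrors the library:

```bash
canyonpool simulate --seed 3 --outdir out/           # VCF/GFF3/TSV/JSON
canyonpool stats --sites out --slopes out/slopes.tsv \
    --genome-length 1000000 --out out/stats.tsv
canyonpool sweep --sites out/SFS_1.vcf --out out/SFS_1.sweeps.bed
canyonpool run-all --seed 3 --outdir out/            # everything at once
```

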