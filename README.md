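# chmarray

SNP-array analysis of **duplicated haploid genomes** — the genomes of
complete hydatidiform moles (CHMs), conceptus tissues that carry two
identical copies of a single sperm's haploid genome. Because every locus is
expected to be homozygous, a CHM genotyped on a SNP array yields a
*definitive haplotype* (no statistical phasing needed), and copy-number
variation must be read from signal intensity alone (B-allele frequency is
uninformative when nothing is heterozygous).

`chmarray` implements the full analysis chain for a CHM cohort genotyped on
two array platforms (an Affymetrix-style platform "A" reporting log2R and
an Illumina-style platform "B" reporting logRR), plus a synthetic-data
generator with known ground truth so every stage is testable end to end:

1. **Haploid QC (HQC)** — on haploid material every heterozygous call is an
   artifact, and hets concentrate at low relative signal intensity
   (homozygously deleted or divergent paralogous regions). HQC profiles the
   het fraction per intensity bin, derives the reliability threshold where
   heterozygosity reaches ~1%, forces all het calls and all calls below the
   threshold to no-calls, and drops duplicate-position markers, markers
   called in <90% of samples, and samples called in ≤96% on either platform.
2. **Platform merge** — shared SNPs are matched by (chrom, pos); platform-B
   annotations on the opposite strand are complemented (A/T and C/G SNPs
   are oriented by allele-frequency matching or excluded); per-sample calls
   merge with discordant pairs forced to no-call.
3. **LD bins and tagSNPs** — haploid r² from direct haplotype counts,
   r² = (f − pq)² / (p(1−p)q(1−q)), for common SNPs (MAF ≥ 5%) within
   300 kb; greedy maximal binning at r² ≥ 0.80 (ldSelect-style); one tagSNP
   per bin by the "avesnp" criterion (maximal mean r² to the other members).
4. **CNV segmentation** — circular binary segmentation (CBS) of each
   sample × platform × chromosome intensity profile with a sequential
   permutation test (α = 0.01, 10,000 permutations); segments crossing a
   centromere are split at it; the loss threshold is derived per platform
   from the valley of the bp-weighted histogram of segment means (fixed
   overrides such as −1 / −2 are supported); gains use the conventional
   0.5 boundary; segments ≤ 50 bp are discarded.
5. **CNV regions** — cross-platform overlap concordance (≥1 bp), size
   correlation of overlapped segments >10 kb, and the state-blind union of
   all CNV segments across samples and platforms ("CNVRs"), with the genome
   fraction they occupy.

## Worked example

`examples/` holds one short narrative script per capability. For instance,
`python examples/04_cnv_calling.py` simulates a 12-sample cohort with four
planted CNVs and runs the whole chain:

```
derived loss thresholds (valley between deletion and neutral modes):
  platform A: -1.4   platform B: -1.9

CNV segments per platform (12 genomes):
platform state  n_segments  per_genome
       A  loss           7    0.583333
       A  gain           3    0.250000
       B  loss           7    0.583333
       B  gain           3    0.250000

cross-platform concordance: 10/10 platform-A segments overlapped by B; 0 opposite-state overlaps
size correlation of overlapped segments >10 kb: r=0.99 (n=10)

CNV regions (union across samples/platforms, state-blind):
  chr1:300000-348000  (8 contributing segments)
  chr1:878425-1146000  (4 contributing segments)
  chr2:200000-348000  (6 contributing segments)
  chr2:1000000-1100000  (2 contributing segments)
regions occupy 20.1% of the toy genome
```

The derived loss thresholds sit in the empty band between the deletion mode
(planted at −3 / −4) and the neutral mode at 0; the four CNV regions
recover the four planted intervals (region boundaries span the first to
last contributing *marker*, hence the slight shrinkage relative to the
planted bp intervals).

A thin CLI mirrors the library: `chmarray simulate|hqc|merge|ldbin|segment|regions|run`,
each stage reading/writing TSV and BED, and `chmarray run --config run.yaml`
executing everything from one YAML config with a master seed and a
checksummed run manifest.

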