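# Methods

## The analysis problem

A complete hydatidiform mole (CHM) carries a duplicated single-sperm
haploid genome. Two consequences drive everything here:

* every true genotype is homozygous, so (i) any heterozygous call is an
  artifact and (ii) each sample's calls are directly a phased haplotype;
* B-allele frequency carries no copy-number information, so CNV detection
  must rely on relative signal intensity alone (log2R on platform A, logRR
  on platform B — both log2 ratios against a reference intensity, and not
  on a common scale across platforms, so the platforms are segmented
  separately and only reconciled at the interval level).

## Haploid QC

Heterozygous miscalls concentrate at low signal intensity: inside a
homozygous deletion there is no target DNA, the probe reads noise, and the
caller frequently emits a het. The het fraction as a function of binned
intensity (bin width 0.1, fine enough to localize a threshold to one
decimal) is therefore sharply elevated below the deleted-region intensity
mode and near the baseline miscall rate elsewhere.

The reliability threshold θ is the upper edge of the highest-intensity bin
whose het fraction reaches the `het_level` (default 1%). Two variants are
provided:

* the plain rule (`significance=None`): het fraction ≥ `het_level`;
* a binomial variant (default in the chained/pipeline runs,
  `significance=0.01`): a bin counts as het-enriched only when its het
  count is *significantly* above `het_level` by a one-sided binomial test.
  Motivation: in sparsely populated tail bins a single stray het call can
  satisfy the plain rule and drag θ into the call bulk; the significance
  test makes the decision depend on evidence, not on one call. On densely
  populated data the two variants agree.

Forcing is strict (`intensity < θ`); a het below θ is tallied once, as
low-intensity. All hets are forced regardless of intensity. Markers sharing
a (chrom, pos) with another marker on the same platform are removed — every
member of the group, since the platform gives no basis to prefer one assay.
Markers with call rate < 90% are removed (exactly 90% is kept); samples are
retained only when called at strictly more than 96% on *both* platforms.
All rates are computed after HQC forcing, once, so the marker and sample
cuts commute.

## Cross-platform merge

Shared SNPs are matched by (chrom, pos) only. Allele-set comparison
classifies each shared SNP: equal sets pass; sets equal after complementing
platform B are strand flips (B's annotation is complemented); anything else
is excluded. Self-complementary A/T and C/G SNPs cannot be oriented from
alleles, so they are oriented by allele-frequency matching — pick the
orientation minimizing |freq_A − freq_B| — and excluded when both
orientations agree within a tolerance (default 0.1) or when the SNP's MAF
is below 0.05 on either platform (frequency matching is then powerless).
This ambiguous-SNP policy is this package's own design choice.

Allele *labels* are aligned separately from strand: a platform may list the
same two alleles in the opposite order, in which case B's homA/homB codes
are swapped before comparison. Per sample and shared SNP: both missing →
missing; one call → that call; equal → that call; unequal → no-call,
counted discordant. The discordance fraction is over pairs where both
platforms made a call. Markers private to one platform pass through, so the
merged set is the union. Excluded shared SNPs (ambiguous/irreconcilable)
are dropped from the merged set entirely: a marker that cannot be oriented
cannot be trusted in a merged haplotype.

With independent opposite-homozygote miscalls at rate *e* per platform, the
expected discordance is 2e(1−e) — the property the simulator's miscall
model reproduces and the tests check.

## LD bins and tagSNPs

Haploid calls make r² a pure counting exercise: with p, q the allele-A
frequencies at two markers over jointly called samples and f the joint
(A,A) frequency, D = f − pq and r² = D²/(p(1−p)q(1−q)); this equals the
squared Pearson correlation of the 0/1 allele indicators (an identity the
tests exploit as an oracle). Pairs are computed for common SNPs
(MAF ≥ 0.05 on the merged calls — the only frequency available) within one
chromosome at ≤ 300 kb; the window applies at pair computation.

Binning is greedy-maximal: repeatedly the unbinned marker with the most
unbinned neighbors at r² ≥ 0.80 seeds a bin of itself plus those neighbors;
ties break by smaller genomic position, then marker id (the tie-break is
this package's choice; reference implementations leave it unspecified).
Leftover markers are singleton bins — the "SNPs without proxies", whose
fraction is singleton bins / common SNPs. The tag is the member with
maximal mean r² to the other members ("avesnp"); member pairs outside the
pairing window count r² = 0 in that mean; singletons tag themselves.

## CNV segmentation

CBS considers, on each current segment of n markers, every arc x[i:j] with
arc and complement at least `min_width = 2` long, and scores
|mean(arc) − mean(complement)| / sqrt(1/k + 1/(n−k)). The common-variance
factor of the usual two-sample statistic is dropped deliberately: it is
invariant under permutation of the segment's values, so it cancels from the
permutation test and the maximizing arc is unchanged. The best split is
accepted when its permutation p-value is ≤ α = 0.01 against `n_perm =
10,000` random permutations, then the pieces recurse. Parameters are pinned
explicitly (α 0.01, 10,000 permutations, min width 2, no smoothing, no
split-undoing) rather than inherited from any historical implementation.

The permutation test runs sequentially in chunks of 500: rejection is exact
as soon as the exceedance count passes ⌊α·n_perm⌋ (it can only grow), and
acceptance stops early once at least 1000 permutations are done and the
Clopper–Pearson 99.9% upper bound on the exceedance rate is ≤ α. The early
acceptance is the one approximation: it can only fire when the true p-value
is below α with 99.9% confidence, so decisions at level α are essentially
those of the full test at a fraction of the cost. The RNG is seeded per
(sample, chromosome) from the master seed, so any single profile re-runs
identically in isolation.

Missing intensities are dropped before segmentation. Segment coordinates
span the first to last contributing marker (array-CNV convention);
inter-marker gaps at segment edges belong to no segment. Segments crossing
a centromere are split at it: the p-arm part ends at centromere start − 1,
the q-arm part begins at centromere end + 1, means are recomputed from each
part's markers, and empty parts are dropped. The ≤ 50 bp size filter is
applied after centromere splitting.

**Loss threshold.** The bp-weighted histogram of segment means (bin 0.1) is
bimodal: a deletion mode well below 0 and a dominant neutral mode near 0.
The published analyses place the boundary at the inflection of cumulative
segment coverage, described only graphically; here it is operationalized
as: find the contiguous nonzero run of bins containing the neutral mode
(the maximum-coverage bin among bins centered above −0.5); among nonzero
bins below that run with upper edge ≤ 0, take the topmost as the deletion
cluster's edge; the threshold is the upper edge of the middle empty bin
between the two. This lands mid-valley, robust to where exactly coverage
peters out. No sub-zero coverage → −∞ sentinel (no losses); no neutral mode
near 0 → error (nothing to bracket against). Fixed overrides (−1, −2)
reproduce conventional choices exactly. Classification is strict
(mean < θ_loss → loss, mean > 0.5 → gain, 0.5 mirroring the loss rule's
strictness), and segments of every state with length ≤ 50 bp are removed.

## CNV regions

Interval arithmetic is 1-based closed throughout: overlap = min(ends) −
max(starts) + 1; BED export converts to 0-based half-open. A segment is
concordant when ≥ 1 bp of it overlaps any CNV segment of the same sample on
the other platform; opposite-state overlaps (gain vs loss — an artifact of
platform-specific reference intensities) are tallied separately. The size
correlation is Pearson on log10 lengths of overlapped pairs where both
segments exceed 10 kb, undefined (flagged) below 3 pairs. CNVRs are the
state-blind union across samples and platforms; bookended intervals
(end + 1 = next start) merge by default because marker-span boundaries make
1-bp gaps artifacts of probe spacing — a flag restores strict-overlap
merging. The genome fraction is region bp over total genome bp from the
genome metadata.

## Synthetic cohort

The generator produces what the pipeline consumes, with truth recorded.

* **Haplotypes**: per LD block, an ancestral pool of K = 6 haplotypes; each
  sample copies one pool member per block (optional per-site mutation).
  This gives high within-block r² and ≈ 1/n between-block r² without
  coalescent machinery — the pipeline needs tunable block LD, not realistic
  genealogies. Pool allele counts respect `maf_floor` (0.05); a floor
  unattainable with the pool size is an error.
* **Duplicated haploidy** is modeled as one haplotype per sample, emitted
  as the corresponding homozygote: the second genome copy is informationally
  redundant.
* **Default scale**: 84 samples (a realistic retained cohort for this kind
  of study), 2 chromosomes × 12 blocks × 25 SNPs (50 kb blocks alternating
  with 50 kb gaps; centromere in the middle gap), ~600 SNP sites. 60% of
  sites are shared between platforms, the rest platform-private; each
  platform adds 15% intensity-only probes; 5 duplicate-position probes are
  injected into platform B; 20% of shared unambiguous SNPs are
  strand-flipped in B's annotation, and B lists allele pairs in swapped
  order for a random half of its sites.
* **CNVs**: four planted intervals (two losses, carrier fractions
  0.30/0.25; two gains, 0.20/0.10) with lengths 50–250 kb so overlapped
  segment sizes carry real variance. Loss shifts −3 (A) / −4 (B), gain
  shifts 0.58 (just above the 0.5 boundary, ≈ log2(3/2)), noise SD
  0.25/0.30. No published quantitative noise model exists for these
  intensities; these values were fixed once as plausible for the two array
  chemistries and give the qualitative features the pipeline exploits
  (well-separated deletion mode, overlapping platform calls).
* **Call errors**: baseline no-call 0.005, spurious het 0.002,
  opposite-homozygote miscall 0.001; inside a carried loss a het is emitted
  with probability 0.40, reproducing the low-intensity het enrichment
  (ratio ≫ 10× below vs above the derived threshold).
* Same seed → byte-identical outputs; the three stages draw from
  independent seed streams, so each stage is reproducible in isolation.

**What the simulator does not emulate** — and hence what passing tests do
not show about real arrays: GC and probe-sequence intensity waves, the
platforms' differing reference-set definitions (which in real data produce
opposite-state overlaps and sub-50% concordance), genuine population LD
decay and allele-frequency spectra, divergent-paralog het calls, batch
effects, and raw probe-level signal. Quantities tied to cohort scale
(bin counts, genome fractions) are therefore order-of-magnitude different
from any real cohort; structural identities (recovery, thresholds falling
in the valley, discordance ≈ 2e(1−e)) are what the tests assert.

## Numerical and design choices

* Genotype alphabet is abstract (homA/homB/het/nocall); nucleotides live in
  the annotation only — merge logic needs allele labels, call matrices
  do not.
* Chromosome inclusion is configuration; nothing is hard-coded beyond the
  natural sort (numeric, then X).
* An arc and its complement describe the same split; the maximizer returns
  the non-wrapping representation and downstream uses only the induced cuts.
* Degenerate inputs: profiles with a single non-missing value yield one
  one-marker segment; monomorphic markers are skipped in r² (undefined, not
  an error); a size-correlation with < 3 qualifying pairs is flagged
  undefined rather than extrapolated.
* Per-stage seeds derive from the master seed by stable hashing of the
  stage name, so adding or reordering stages does not shift other stages'
  randomness.

## Known limitations

* The loss-threshold valley rule needs an empty band between the deletion
  and neutral modes; heavily mosaic samples (continuum of segment means)
  would require the fixed-threshold override.
* CBS here is the exact O(n²)-per-test formulation; profiles of ~10⁵
  markers per chromosome would need the windowed/hybrid approximations
  used by production segmenters.
* A/T and C/G SNPs near 50% frequency are unrecoverable by design and are
  excluded rather than guessed.
* The merge drops excluded shared SNPs entirely instead of keeping one
  platform's copy; with real annotation, rsID-based rescue would be the
  next step (positions are the only join key here).
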