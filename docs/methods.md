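# Methods

## The cross model

Meiosis of the heterozygous A×B diploid is simulated as a four-strand
bivalent per chromosome: the two homologs replicate into four chromatids
(two A sisters, two B sisters); the crossover count per bivalent is
Poisson with mean `2 × L`, where `L` is the chromosome's genetic length
in Morgans, so each meiotic product experiences `L` expected exchange
points; crossover positions are uniform on the physical chromosome and
each crossover joins one uniformly chosen chromatid of each homolog.
There is no crossover or chromatid interference and no gene conversion.
Consequences used throughout:

* every biallelic marker segregates exactly 2:2 within a tetrad
  (structural — the four chromatid labels are always a permutation of
  {A, A, B, B});
* the two-point recombination fraction follows Haldane's map function
  `r = (1 − e^(−2d))/2` (each crossover involves a given chromatid with
  probability 1/2, so exchange points per chromatid are Poisson(d));
* chromosomes assort independently (chromatids are permuted into spores
  per chromosome), so with zero genetic length each spore carries whole
  parental chromosomes but is still a genome-wide mosaic.

Genetic lengths come either from an explicit per-chromosome table in
Morgans or from a constant rate, default 0.35 cM/kb — the commonly used
genome-wide average for *S. cerevisiae*.

## Phenotype model

A single trans-acting repressor locus controls a binary expression
state.  A haploid spore carrying the repressor parent's allele at the
causal marker is "off" (level 0); all other spores are "on" at
`base_level` (default 100 arbitrary units).  Dominance matters only in
the diploid: a dominant repressor silences the heterozygote.  Among
expressors, the level is multiplied by `cis_boost` (default 2.0) when
the whole linked cis region derives from the designated parent — the
cross this emulates showed higher expression from one parent's promoter
haplotype among expressing segregants, but no quantitative effect size,
so the boost is a free simulation parameter.  The all-markers-from-one-
parent rule for the cis region is deliberate: a recombinant promoter
haplotype is treated as non-boosted.  Level noise is off by default; a
lognormal multiplicative term (`noise_sigma`) is available.

## Pooled sequencing emulation

Pools are equimolar by default (an optional per-member weight vector
models pooling inaccuracy).  Per marker and pool, read depth is
Poisson(`coverage`) (a fixed-depth mode exists for exact tests); each
read derives from a uniformly chosen pool member, so the allele-B read
count is Binomial(depth, B-fraction of the pool).  Two artifacts are
modeled, in this order:

1. **reference-mapping bias** — a read whose *true* allele is not the
   mapped reference's allele is lost with probability `ref_bias`
   (default 0.05).  Dropout is applied to the true allele because the
   artifact it mimics is alignment failure of diverged reads;
2. **sequencing error** — a surviving read reports the wrong allele
   with probability `error_rate` (default 0.002).

Applying dropout before error reflects the physical pipeline (a read
must align before it can be miscalled).  The defaults are ordinary
short-read values: ~50× pool coverage, Q27-ish effective per-site error,
and a mild mapping loss for ~0.3%-diverged genomes.

## Allele frequencies and region calling

The allele frequency at a marker is reported relative to the genome
being mapped to: the fraction of reads supporting the *non*-reference
parent's allele.  Markers below `min_depth` (default 10) are no-calls.

Mapping the same pool against both parental references produces two
estimates of one underlying pool frequency whose mapping bias points in
opposite directions.  The region caller therefore **combines the counts
across orientations** into a depth-weighted frequency per pool before
testing concordance (`mode="combine"`, the default); this is the
efficient estimator and cancels reference bias to first order.  A
`strict` mode instead requires the test to pass under every orientation
separately, and a single-orientation profile degrades gracefully to a
single-reference scan.

A marker is concordant when the combined frequency of the non-repressor
parent's allele is ≥ 1−ε in the expressing pool and ≤ ε in the
non-expressing pool (ε default 0.02, sized to tolerate roughly one
error read at 50×).  Candidate regions are maximal runs of at least
`min_snps` (default 2) concordant markers on a chromosome; a run may
bridge up to `max_gap` (default 2) consecutive non-concordant markers.
The bridge covers both low-depth no-calls and isolated sub-threshold
markers: at Poisson coverage a depth-49 marker fails ε = 0.02 on a
single error read, so demanding strictly consecutive concordance
shatters the truly fixed interval into fragments, while genuine
recombination breakpoints discord over long marker stretches and still
terminate runs.  Region boundaries are SNP-bounded (first to last
concordant marker), a conservative convention; no windowed or smoothed
statistic enters the call — the criterion is exact fixation, though a
windowed allele-frequency-difference track is emitted for plotting.
With 14+14 pools the probability an unlinked marker is concordant at
high coverage is 2·(1/2)²⁸ ≈ 1.5 × 10⁻⁸, so spurious regions are
negligible; `min_snps = 2` additionally suppresses singleton artifacts.

`contains_causal` (simulations only) is positional: the region span
covers the causal marker's position on its chromosome.

## Segregation statistics

Single-locus control is checked structurally (every tetrad 2 on : 2
off) and across all spores with an exact two-sided binomial test of 1:1
segregation, appropriate at tetrad-dissection sample sizes.  The
two-sided p-value follows the minimum-likelihood convention (sum of the
probabilities of all outcomes no more likely than the observed one), so
the most central outcome — 14 of 28 — gives p = 1.  Dominance is called
from the heterozygous diploid: the parent whose state the diploid
matches is dominant; identical parental states are an error, not a
call.

## Expression analytics

* **DE calling** — a gene is DE in a comparison when `padj ≤ padj_max`
  (default 0.0005) and the average of the two condition means is
  ≥ `min_mean` (default 100 normalized reads; 50 is the customary
  antisense-transcript setting).  Adjusted p-values are consumed as
  given; a Benjamini–Hochberg helper exists for raw-p tables.
* **Dependence classes** — `dependent = de_wt \ de_del`,
  `deletion_only = de_del \ de_wt`, remainder independent.  The classes
  partition the universe and satisfy |dependent| + |overlap| = |de_wt|.
* **On/off calls** — a strain is on at ≥ `on_min`, off at ≤ `off_max`
  (thresholds must satisfy `on_min > off_max`); transcripts on in
  exactly one strain are the extreme expressors.  A sweep mode reports
  extreme counts across a threshold grid rather than fixing one pair.
* **TSS-proximal SNPs** — a transcript counts when ≥ 1 SNP lies within
  `window` bp of its TSS, inclusive on both boundaries and symmetric in
  both directions (default 50 bp).
* **Promoter SNP density** — SNP count, length and SNPs/kb per
  intergenic region, ranked by count with ties broken by density then
  name for determinism.
* **Synonymous/nonsynonymous** — each SNP inside a CDS is classified by
  translating the reference and alternate codon under the standard
  genetic code (premature stops are nonsynonymous).  CDS are assumed
  contiguous and intronless (the usual yeast case), stored as the
  +‑strand genome slice; minus-strand genes are reverse-complemented
  before codon lookup.  SNPs whose reference allele disagrees with the
  stored CDS are skipped with a warning.
* **Best-fit distances** — the line of best fit is an OLS regression on
  log2(count + 1) over *all* genes; each subset gene's distance is its
  absolute vertical residual.  Orthogonal (total-least-squares) distance
  is available behind `method="orthogonal"`; OLS is the default because
  "linear regression" implies vertical residuals.
* **Cumulative DE** — per-comparison empirical CDFs of |log2FC| over a
  gene subset; the stochastic-dominance summary is the signed area
  between two ECDFs, which equals the difference of mean |log2FC|.

## Synthetic scenarios

The default scenario mirrors the study shape this package emulates: a
16-chromosome genome with real *S. cerevisiae* chromosome lengths
(12.07 Mb), Poisson-spaced markers at mean 2 kb (~6,000 SNPs — well
above 1 marker/20 kb), refB coordinates offset per chromosome by a
constant (order-preserving stand-in for indel drift), the causal
repressor nearest chrVIII:50,000 (left arm), 7 tetrads → 28 segregants
pooled 14+14, sequencing at the defaults above.  DE tables for seven
comparisons plant 1207 wildtype-DE genes of which 822 are dependent,
200 deletion-only genes, 62 extreme expressors (the first of which is
an on/off locus whose promoter receives 21 planted SNPs plus one at the
TSS and doubles as the cis region), 3 allele-swap responders, and an
asymmetric deletion response (all dependent genes respond to the
background-A deletion, a 1/3 subset to background-B).  Padj values are
drawn Beta-distributed below threshold for planted DE genes and above
threshold otherwise — the DE test itself is out of scope, so recovery
of the planted sets by thresholding is exact by construction, which is
the point: the set logic, not the test, is being validated.  One master
seed drives per-stage child streams, so bundles are byte-identical per
seed.

What the generator does **not** emulate: real genome sequence content,
linkage disequilibrium beyond the cross itself, gene conversion,
aneuploidy, spore death, correlated mapping artifacts between the two
references, overdispersed sequencing depth, and noisy p-values.
Passing tests therefore demonstrate the correctness of the inference
logic under the stated noise model, not robustness to every artifact of
real pooled sequencing.

## Numerical and degenerate-input conventions

Internal coordinates are 1-based inclusive everywhere; BED is 0-based
half-open at the file boundary only.  Threshold comparisons are
inclusive (≤/≥).  Zero-coverage simulation returns an empty count table
with a warning; depth-0 frequencies are NaN; uniform phenotypes make
pooling an error (mapping is impossible); identical parental states
make the dominance call an error; constant X expression makes the
best-fit line an error.  Scans at desk scale run in milliseconds; a
full default scenario generates in ~1 s on one CPU.

## Problem sizes used in the checks

The test suite exercises the method at the study's own scale: 100
seeded full scenarios for region recovery (expecting a single region as
the modal outcome and ≥95% causal containment), 10⁵ spores for the
Haldane map-function comparison, 10⁴ sequencing replicates for the
balanced-pool frequency check (both at 3 Monte-Carlo standard errors),
and brute-force oracle comparisons up to 10³ markers.
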