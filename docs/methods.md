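# Methods

## The analysis in one paragraph

A biparental RIL population is phenotyped, the k most extreme lines on
each side are pooled, and the pools plus parents are sequenced. With the
black-seeded parent as reference, every informative SNP is fixed REF in
one parent and ALT in the other, so the bulk's ALT-read fraction
(SNP-index) estimates the yellow-allele frequency among the pooled lines.
Δ(SNP-index) between bulks, smoothed over sliding windows and compared to
a simulated no-QTL band, localizes trait loci as runs of windows whose
mean Δ exceeds the 99% cutoff.

## Simulator (`simbulk`)

**Population.** Each RIL starts as an F1 (one intact haplotype per
parent) and is advanced by single-seed descent: per generation, two
independent gametes are drawn from the current individual. Meiosis is
Haldane — crossover count ~ Poisson(genetic length in Morgans), positions
uniform, no interference, no crossover-position memory between
generations. F₂:₁₁ is modelled as 10 selfing generations, leaving
residual heterozygosity (1/2)¹⁰ ≈ 9.8 × 10⁻⁴ per locus; chromosomes are
mosaics of parental-origin segments stored as breakpoint lists.

**Traits and bulks.** Traits are additive: trait = Σ aᵢgᵢ + ε, with
gᵢ ∈ {−1, 0, +1} the yellow-dosage coding and ε ~ N(0, σ²). A QTL can be
given its additive effect directly or a target fraction of trait variance;
targets are converted assuming Var(g) = 1 (exact for fully inbred lines),
with total variance T = (Σa²_explicit + σ²)/(1 − Σtargets). Realized r²
per QTL is reported so a user can see the sampling spread at n = 188.
Bulks take the k largest and k smallest trait values; boundary ties break
toward the smaller line identifier, and the low bulk is drawn from the
lines left after the high bulk so the two can never intersect.

**Reads.** Per site and sample, depth ~ Poisson(mean) and ALT reads ~
Binomial(depth, p(1−ε) + (1−p)ε), where p is the ALT-dosage fraction
among the 2k bulk haplotypes (0 or 1 for the parents) and ε the
sequencing error rate, applied symmetrically. Defaults mirror the study:
188 lines, k = 25, bulk depths 41× (high/yellow) and 44× (low/black),
parents 30× (the study sequenced parents shallower than pools; 30× is a
typical parental depth for this design), ε = 0.005 (mid-range Illumina
error after filtering). Site-quality annotations (QD, FS, MQ, MQRankSum,
ReadPosRankSum) are drawn from a "clean" mixture, except for a
configurable artifact fraction (default 5%) drawn to fail exactly one
hard-filter rule; clean and artifact ranges are disjoint, so filter tests
have exact expected counts. The VCF writer emits fixed-precision text so
identical configurations are byte-identical; one root seed feeds separate
child streams for population, trait and reads.

**What the simulator does not model.** Read mapping and calling (depths
are Poisson, not alignment-derived; no reference bias, paralogy or
repeat-driven artifacts beyond the planted annotation failures), epistasis
and maternal effects on the trait, crossover interference, segregation
distortion, and non-equimolar DNA pooling. Passing tests therefore show
the statistics behave correctly under the idealized design, not that real
libraries are free of mapping pathologies.

## Filters (`variant_filtering`)

Hard-filter thresholds use strict inequalities (QD < 2.0, FS > 60.0,
MQ < 20.0, MQRankSum < −12.5, ReadPosRankSum < −8.0); boundary values
pass, and absent annotations pass (rank-sum statistics are undefined at
sites without mixed genotypes — the caller convention). The depth
criterion uses DP when present, else the AD sum. Multi-allelic records
are dropped globally: the SNP-index is defined for a single ALT allele
and the cross is biparental. The reference-consistency criterion is
implemented as "reference-role parent is homozygous 0/0", which
generalizes "the black parent matches its own assembly" to any reference
choice. Both filters are pure per-record predicates, so their order
cannot change the kept set.

## Genome scan (`qtlseq_core`)

**Windows.** Anchors at 1, 1+s, 1+2s, … with half-open spans [a, a+W);
only full-width windows are emitted unless the chromosome is shorter than
W, in which case a single truncated window covers it. Window means are
unweighted over member SNPs. Defaults W = 1 Mbp, s = 10 kbp, minimum 10
SNPs per window.

**Null band.** Per window and replicate: each bulk's ALT count among k
pooled lines is Binomial(k, ½) — lines are treated as homozygous, since
residual heterozygosity at F₂:₁₁ is < 0.1% — the bulk's index is a
binomial read draw at the window's total member depth, and the cutoffs
are nearest-rank 95th/99th percentiles of |Δ| over replicates (default
100,000; nearest-rank is stated because its granularity is visible in the
third decimal). The pooled composition is drawn **once per window, not
per site**: all sites in a window descend from the same 2k sampled
haplotypes, and at RIL map densities a 1-Mbp window spans only a few cM,
so within-window allele frequencies in the pool are nearly perfectly
correlated. Drawing compositions independently per site and averaging
would shrink the null by √n_SNPs and flag most of a null genome as
significant; the window-level draw reproduces the observed null variance
(sd ≈ √(2·¼k) ≈ 0.14 at k = 25, giving a 99% cutoff near 0.36 at these
depths) and collapses to the per-site two-stage binomial for single-SNP
windows. Residual conservatism (within-window recombination makes
observed means slightly tighter than the complete-linkage null, and the
error rate shrinks |Δ| by 1−2ε) is measured by the calibration
experiment and sits well inside its Monte-Carlo tolerance.

Numerical choices: read draws switch from exact binomial to the clipped
normal limit above a total depth of 200, where the approximation error is
orders of magnitude below Monte-Carlo noise; replicates are processed in
chunks of 20,000 to bound memory; one composition replicate stream is
shared across windows, and cutoffs are cached by the window's total depth
pair so repeated profiles reuse draws.

**Regions.** A window is significant when mean Δ > cutoff at the chosen
level (positive exceedance by default — the causal signal is positive
under this polarity; a two-sided flag uses |mean Δ|). Maximal runs of
consecutive emitted significant windows form regions; windows skipped for
low SNP count do not break a run. Because windows are ~100× wider than
the step, two runs separated by a single sub-threshold window still
overlap in base pairs; the pipeline unions physically overlapping calls
before reporting. Each region reports the member window with the largest
mean Δ as its peak and peak difference = peak Δ − that window's P < 0.01
cutoff. Span summaries are reported in Mbp at 2 decimals.

## Annotation (`variant_annotation`)

One canonical transcript per gene (longest CDS). Context precedence when
a position matches several features, possibly of different genes:
CDS > UTR > intron > upstream > downstream > intergenic. Upstream and
downstream are the 1-kb flanks beyond the TSS/TTS, strand-aware and
inclusive of the 1,000th base. SNP effects rebuild the affected codon
from the spliced CDS in transcript orientation and translate with the
standard nuclear table; stop gain/loss are reported separately from
nonsynonymous. Indels fully inside the CDS are frameshift iff the length
difference is not a multiple of 3; indels touching a CDS boundary are
"not_applicable" (no splice model). Incomplete CDS (length not a multiple
of 3) yields "not_applicable" with a warning. Coordinates are 1-based
inclusive throughout (GFF3 convention).

## Mapping utilities (`mapping_utils`)

Pearson goodness-of-fit χ² with df = classes − 1 and an optional Yates
correction (off by default; two classes only). Interval widths and
marker-map spacing report at 2 decimals; mean adjacent spacing is
span/(n−1), the standard definition for n ordered markers. For the
published F₂:₃ and BC₃F₂ seed-color counts against 1:3, the direct
statistic gives 4.07 and 6.68 — the tests freeze these computed values.

## Pipeline and validation experiments

`cli_report.run_pipeline` executes filter → SNP-index → windows → band →
regions (plus optional annotation and plotting) from one TOML config,
writing a manifest with parameters, seed, input checksums and per-stage
counts; identical config and seed give byte-identical outputs.

`experiments` re-runs the full simulate-and-scan loop at the design
conditions on deliberately compact genomes (two to three chromosomes of
30–50 Mbp, 1,000–1,200 sites each, 10,000-replicate bands) so a replicate
set completes in minutes on one core; the properties checked — per-window
false-positive rate, per-replicate recovery of a 45%-variance QTL,
heterozygosity decay and the Haldane–Waller two-locus recombinant
fraction at 50,000 lines — do not depend on total genome length. Null
calibration is assessed with the genome as the Monte-Carlo unit: windows
within a genome overlap and share the bulks' genome-wide composition, so
exceedances arrive in bursts and a per-window binomial error would be
badly overconfident.

## Known limitations

- The null band conditions on complete within-window linkage; for
  organisms or window sizes where a window spans ≳ 20 cM it would be
  conservative, and the per-site limit would need reinstating.
- Depth-weighted versus unweighted window means differ negligibly at
  40×; the unweighted form is used for the observed profile and the
  depth-weighted total for the null's read stage.
- The annotator handles one transcript per gene and no splice-site,
  start-loss or regulatory categories.
- No LOD-based interval mapping or linkage-map construction — the scan is
  the bulked-segregant statistic only.
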