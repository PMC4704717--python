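# Methods

`cenchrom` re-implements, as a tested pipeline, the window-based analysis of
centromeric chromatin from CENH3 (CENP-A-type) ChIP-seq: domain and
subdomain calling, nucleosome positioning and phasing on the centromeric
satellite repeat, MNase cut-site profiling, and integration with gene
annotation, histone marks and centromere-expansion intervals.  Every stage
is driven and validated by a synthetic-genome generator in which the
quantities the analyses estimate are planted and recorded, so the whole
stack is verifiable without the original sequencing data.

## The synthetic genome and chromatin model

`synth.generate_genome` builds chromosomes of i.i.d. random sequence and
plants, per the configuration:

- **Satellite arrays** — exact tandem copies of a 156-bp monomer.  The
  packaged monomer (`SYNTHETIC_CENTC_MONOMER`) is a synthetic stand-in
  generated once with a frozen RNG at 55.1% A/T; it is not a published
  consensus, and nothing downstream depends on its base identity beyond
  composition and tandem structure.
- **Unmappable regions** — whole 10-kb windows of centromeric non-array
  sequence are copied into a dump segment appended to the chromosome, so
  that exact 150-mer uniqueness (the mappability model below) fails inside
  them.  Blocks are chosen until the unique fraction of each centromere
  reaches the configured value (default 0.53); tandem arrays count toward
  the non-unique share.  Aligning blocks to analysis windows makes the
  planted mappable percentage essentially deterministic.
- **CENH3-depleted subdomains** — intervals inside centromeres whose
  nucleosomes are canonical H3.  The maize-like preset plants the published
  per-centromere totals (110/128/79/125/184/69/151 kb; 846 kb) as two
  alternating subdomains per centromere, each shorter than the 100-kb
  island merge gap so depleted stretches do not split the assembled
  centromere, starting on 10-kb boundaries and ≥ 200 kb from centromere
  ends so the edge filter cannot erase planted truth.
- **Genes, marks, expansion flanks** — 21 genes inside depleted subdomains
  (11 active), 13 inactive genes in enriched regions; euchromatic-mark
  peaks (H3K4me3/H3K36me3/H3K9ac) on every active gene plus one H3K27me3
  peak; for four chromosomes, a 400-kb "expanded" flank with one active
  gene against a matched "nonexpanded" flank with eight, generating the
  euchromatin deficit the expansion bootstrap is meant to detect.

`plant_nucleosomes` places one nucleosome per monomer inside arrays at
monomer offset 78 (the monomer midpoint; only monomer-scale phasing, not
the intra-monomer offset, is constrained by data) with Gaussian jitter
(default sd 5 bp), and sequential nucleosomes elsewhere with gaps
N(190, 20²) truncated at 147 bp.

`simulate_library` emits fragment coordinates directly — read simulation
and alignment are out of scope, and the real-data entry point is
pre-aligned BED/BAM.  ChIP fragments sample nucleosomes with weight
`chip_enrichment_fold` (default 30) for centromeric CENH3, times
`depletion_fold` (default 0.1) inside depleted subdomains, weight 1
elsewhere, plus a 2% uniform positional background; input weights are
uniform.  Fragment lengths come from a Gaussian mixture with modes
147/133/123 bp (weights 0.7/0.2/0.1, sd 4); the "underdigested" flag adds
an 11-bp linker remnant, moving the main mode to 158 bp.  Naked-DNA
digestion is a cut-site process: the 5′ cut position is drawn with odds
`at_cut_bias` : 1 (default 12) for A/T versus G/C, and the 3′ boundary is
drawn from an 11-bp window around the target length with the same base
weighting, so both fragment ends carry the bias.  Fragment midpoints get a
3-bp digestion jitter.  All randomness flows from one seed; identical
configuration and seed reproduce outputs byte for byte.

**What the generator does not emulate**: sequencing errors, PCR
duplicates, mismatch-tolerant mappability, real MNase kinetics (the
0.2 U/5 U distinction is only a length shift), GC-coverage bias, diploid
variation, and satellite higher-order structure.  Passing tests therefore
demonstrate the *estimators* recover planted parameters under the stated
noise model — not that real libraries satisfy that model.

An important scale effect: observed window enrichment equals the sampling
weight divided by the genome-average weight, so a desk-scale genome whose
centromeres are ~half its length cannot display a 30-fold mean centromeric
enrichment (in a real ~2.3-Gb genome centromeres are ~0.5% and weight ≈
observed fold).  The fold-recovery test uses a small-centromere
configuration for exactly this reason; the subdomain caller normalizes
centromere-locally and is insensitive to the effect.

## Mappability

A position is mappable iff its 150-mer occurs exactly once counting both
strands — the deterministic limit of the sample-and-realign procedure,
chosen to remove sampling noise.  The implementation hashes every k-mer
(64-bit polynomial rolling hash with frozen constants) and counts pooled
forward and reverse-complement hashes; unit tests require exact agreement
with a brute-force counter on small genomes.  k-mers containing non-ACGT
bases are unmappable; a reverse-complement palindrome occurring once
counts twice and is unmappable.  10-kb windows are "mappable" when ≥ 50%
of their positions are unique (`min_frac`; the window-level criterion is
not pinned down by any external source, so it is exposed as a parameter),
and per-window fractions are retained for density normalization.

## Domains and subdomains

**Island calling** (SICER-style, 1-kb windows, 3-kb gap, effective genome
fraction 0.7, FDR 0.05): per window the expected count is
max(input-scaled count, effective-genome-average ChIP rate); windows with
upper-tail Poisson p < 10⁻³ are eligible; eligible windows separated by at
most the gap merge into islands.  The island statistic is the Poisson
upper tail of the summed counts over the island's *eligible* windows
(gap windows would dilute genuine islands), Bonferroni-scaled by the
number of analyzed windows, then filtered by Benjamini–Hochberg at the
FDR.  This replaces SICER's E-value machinery with a deliberately
conservative scan correction: on uniform chip-equals-input null data the
caller returns zero islands in ≥ 99% of simulated datasets.  The
eligibility threshold (10⁻³) is this implementation's choice; broad
domains at realistic enrichment are orders of magnitude beyond it.

**Centromere assembly**: islands separated by < 100 kb are merged (gaps
arise from unmappable repeats), then remnants < 30 kb are discarded —
merge before size-filter, in that order.

**Depleted subdomains** (10-kb windows): within called centromeres, only
mappable windows are tested.  λ_w = input_w × r, with r the ChIP/input
total ratio over mappable centromeric windows (centromere-local by
default; a global option exists).  The depletion p-value is the Poisson
lower tail P(X ≤ chip_w | λ_w); the stringent raw threshold 10⁻⁵ is
applied without multiplicity correction.  Adjacent significant windows
merge; portions overlapping unmappable windows are discarded; subdomains
within 200 kb of a centromere end are discarded.  Window quantization
rounds recovered lengths up to window boundaries: on the preset, 846 kb
planted is recovered as 860 kb (partial windows with ≳ 25% depleted
coverage are correctly flagged), i.e. 15.6% of the 5.52 Mb of mappable
centromere versus the planted 15.3%.

## Nucleosome positioning and phasing

Fragments are trimmed to 40 bp around their midpoint; coverage is low-pass
filtered by keeping the lowest `pc_keep_comp` fraction of Fourier
components (0.01 genome-wide, 0.02 on arrays to resolve 156-bp-spaced
peaks).  This is a simplified reimplementation of the nucleR idea — only
positional recovery, not score parity with nucleR, is claimed.  Peaks are
strict local maxima above the mean filtered depth (the DC component is
kept, so the filtered mean equals the raw mean).

The phasogram is the histogram of pairwise fragment-midpoint distances
(lags 1..2000), computed by FFT autocorrelation of the midpoint-count
track and verified exactly against O(n²) pair enumeration.  Periodicity is
estimated by a harmonic comb: after subtracting a 151-bp running-median
baseline (which absorbs the finite-region decay and the steep small-lag
peak from same-nucleosome pairs), the score of period T is the mean
residual at lags {T, 2T, 3T}; lags < 50 bp are ignored.  The best T in
100–300 bp wins, ties to the smaller period, and the result is only
"periodic" when the score exceeds 4 standard errors of the residual noise
— white-noise midpoints are tagged "no periodicity".  The comb was chosen
over reading a single peak because phasogram peaks decay and broaden with
lag; the median baseline was chosen over a linear detrend because the
small-lag peak otherwise dominates both fit and noise estimate.

## Satellite cut-site profile

The consensus monomer is a per-position majority vote over equal-length
copies (ties A<C<G<T); copies with indels are rejected — an intentional
substitution-only model standing in for assembly-based consensus building,
sufficient for the statistic.  Both boundaries of every fragment count as
cuts ("one or both ends" is not externally pinned down; both is the
default).  Cuts inside an annotated monomer map to site g − start + 1
(plus strand) or end − g (minus strand); counts pool over all copies.  The
top ⌈0.2·L⌉ = 32 sites by count (ties to smaller position) are scored for
A/T identity.  On the preset, naked digestion at the default bias gives
100% A/T among top sites versus ~56% for ChIP — reproducing the direction
and approximate magnitude of the naked/ChIP contrast, which depends on the
real monomer's composition and is not claimed numerically.  Monomer
annotation can also be produced by substitution-only scanning of the
consensus (≤ 15% mismatches) for modest regions.

## Annotation integration

Genes are classed as depleted/enriched when ≥ 50% of the gene body
overlaps the respective compartment (the membership rule is this
package's choice), else boundary; active means FPKM ≥ 1 in any tissue
(chosen because 1.1 is the lowest validated expression level in the
study's ground truth; exposed as `active_fpkm`).  Mark islands are
intersected with depleted subdomains after clipping to centromeres.  The
expansion comparison takes per-1-kb-window read densities, normalized by
window mappability, on the expanded and matched nonexpanded flank; the
two-tailed bootstrap p is 2·min(P(Δ*≤0), P(Δ*≥0)) over B = 10,000
resamples of each vector, floored at 1/B.  With ≥ ~100 windows per side
the empirical type-I rate at α = 0.05 is within 5% ± 2%; below ~30 windows
the routine refuses to run.

## Problem sizes and numerical choices

The packaged preset is desk-scale by design: a 22-Mb genome (10.42 Mb of
centromere per the published table, 0.5-Mb flanks, plus the duplication
dump) and 2M + 2M ChIP/input fragments — enough that every planted 10-kb
window decision is ≥ 6σ from its threshold, making recoveries
seed-stable.  Phasing checks use 20,000 fragments on a 200-copy array and
50,000 on a 1-Mb non-satellite centromere.  Poisson tails come from
`scipy.stats.poisson` (`sf`/`cdf`); BH from `statsmodels`.  Degenerate
inputs: zero-length regions yield zero nucleosomes; empty libraries are
errors for enrichment, empty interval sets propagate as empty outputs;
fragments shorter than the trim width are kept untrimmed (warning), which
also makes center-trim idempotent.

## Known limitations

Real-data behavior of the depleted-subdomain test depends on input-library
overdispersion that the Poisson model ignores; SICER/MACS2 consensus
calling is approximated by the single island caller; nucleR score
semantics are not reproduced; the satellite consensus stand-in precludes
comparing absolute cut-site percentages with published values; expression
is consumed, never computed.
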