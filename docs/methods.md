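# Methods

This note documents the models, conventions and numerical choices behind
`recessmap`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic data do and do not
establish about real data.

## Study design being modelled

The package targets the classic mapping design for a fully penetrant
autosomal recessive trait in a closed breeding population: a handful of
affected individuals (default 7) presumed inbred to a single founder, an
equal number of unaffected controls, a dense biallelic SNP array, whole-
genome sequencing of one affected proband, a small panel of unrelated
genomes (default 12) used as a "mutation must be absent elsewhere" filter,
and genotyping cohorts of a few hundred animals for validation. All
coordinates are 1-based closed (VCF/HGVS convention) internally; BED's
0-based half-open convention is applied only at the file boundary.

## Marker QC

Samples with call rate < `sample_call_rate_min` (0.90) are removed first;
all marker statistics are then computed on the remaining samples, making
the audit trail deterministic. Marker rules: call rate < 0.90, MAF < 0.05
(computed over all samples, the usual default when the affected class is
tiny), and Hardy–Weinberg deviation in the controls at p < 10⁻⁵.

The HWE test is the two-sided conditional exact test (the `--hwe` exact
test convention, no mid-p correction): conditional on the observed allele
counts, the p-value sums the probabilities of all heterozygote counts at
most as probable as the observed one. The distribution is built by the
standard two-directional recurrence from the modal count; a relative
slack of 1e-9 is used when ranking equal-probability configurations so
floating round-off cannot drop an exactly tied tail atom. The test suite
checks the implementation against an exact-integer enumeration oracle for
every genotype table of up to 30 diploids (tolerance 1e-12).

## Allelic association and max-T permutation

The per-marker statistic is the Pearson χ² (1 df) on the 2×2 allele-count
table, without continuity correction; missing genotypes drop both of a
sample's alleles at that marker. Tables with a zero margin return
χ² = 0, p = 1 with a `degenerate` flag rather than raising — monomorphic
markers should not crash a genome scan.

Family-wise correction uses max-T permutation: phenotype labels are
permuted (genotypes fixed), each permutation's genome-wide maximum χ² is
recorded, and marker m gets `p_corr = (1 + #{max ≥ χ²_m}) / (1 + N)`.
The (1+k)/(1+N) estimator avoids exactly-zero p-values. The whole
permutation pass runs in float64 so that a permutation reproducing the
observed table compares exactly equal at the max-statistic boundary; the
permutation stream is a deterministic function of (seed, N, n_samples)
only, so results are bit-reproducible. Stratification is *reported* via
the genomic inflation factor λ = median(χ²)/F⁻¹_χ²₁(0.5) ≈ median/0.4549
and deliberately not corrected — the design accepts related cases.

Raw p-values from small allele-count tables are discrete and slightly
conservative; exact uniformity under the null is therefore not a theorem.
The calibration tests assert the tail property P(p < α) ≈ α on a cohort
large enough for the χ² asymptotics (200 vs 200) and bound the
Kolmogorov–Smirnov distance to uniform at 0.05 instead of testing strict
uniformity. For the same reason `p_corr ≥ p_raw` is checked on genome-
scale panels, where the max-statistic guarantees it in practice, but is
not asserted as an algebraic invariant for one-marker inputs.

## Shared-homozygosity mapping

A marker is *compatible* iff no case is heterozygous and all non-missing
case genotypes are the same homozygote. Missing case calls are treated as
compatible — at 1–2% array missingness, a strict rule would shatter true
IBD segments — but a marker where every case is missing breaks the run,
since missing data alone cannot attest sharing. Runs are maximal
stretches of compatible markers per chromosome; controls play no role.
The critical interval is the closed span between the nearest flanking
discordant markers (their own positions, matching the convention of
quoting the flanking heterozygous markers as bounds); when a run touches
a chromosome end the terminal marker is used and a truncation flag set.
Interval lengths are reported in Mb, rounded half-up to two decimals.

Known limitation: the sharing criterion is *strict* — a single discordant
genotype (e.g. one miscall in one case) splits a run. Probabilistic
ROH/HMM callers tolerate isolated errors; they are out of scope here. At
the generator's default per-call error rate of 10⁻³, a ~220-marker
planted segment contains ≥ 1 discordant case miscall in roughly half of
the replicates, so exact recovery of both interval bounds succeeds in
roughly 40–45% of runs; the run always overlaps the true segment, and the
prioritization cascade is unaffected when given the true interval. This
is a property of strict-identity run calling under miscalls, not of the
sample size.

## Hard filters and the cascade

The three filter families label raw variant calls: (i) `HardToValidate`
when MQ0 ≥ 4 and MQ0/DP > 0.1 (DP = 0 with any MQ0 reads is treated as an
infinite ratio and labelled); (ii) `LowQual` when QUAL < 30.0, QD < 5.0,
HRun > 5, or SB > 0.00 — all strict inequalities, so SB = 0 passes;
(iii) `SnpCluster` for membership in any set of ≥ 3 SNVs spanning ≤ 10 bp
(coordinate difference; indels neither count toward nor receive the
label; cluster size 3 follows the common toolchain convention). Labelled
records are dropped *before* the cascade, so step counts are over
retained calls.

Cascade steps are pure intersections (order changes only the intermediate
counts, never the surviving set): proband homozygous-alternate → inside
the critical interval → panel-absent → non-synonymous. "Absent from the
panel" means no panel genome carries the alternate allele in any dose; a
missing panel genotype does not exclude (absence of evidence), but the
number of missing panel calls is kept in the report for audit.

## Consequence annotation

Coding variants are expressed in CDS (c.) coordinates. Deletions and
insertions are shifted to their 3′-most equivalent position inside
repeated sequence before naming (the HGVS rule). SNVs are classified by
in-frame codon comparison; a length change not divisible by three is a
frameshift named `p.<wt><pos><new>fs*<n>`, where `pos` is the first codon
whose amino acid changes (position 1 of the frameshifted peptide) and the
new stop sits at relative position `n` — hence `p.Q2798Rfs*3` puts the
stop in codon 2800 and the mutant ORF at 2,799 residues. ORF lengths
exclude the stop codon on both sides, so truncation deltas are
stop-convention independent. A frameshift with no downstream stop is
reported as `fs*?` with a flag. In-frame indels are classified `other`;
their full HGVS naming (and splice/UTR effects generally) is out of
scope. Single-letter amino-acid codes are used throughout, matching the
compact notation common in mapping reports.

The package ships two *synthetic* reference transcripts (random sense
codons with the relevant codons pinned): a 3,620-codon CUBN-like CDS in
which `c.8392delC` yields `p.Q2798Rfs*3` and an 821-codon truncation, and
a 1,456-codon MRC1-like CDS in which `c.2143C>T` yields `p.R715*`,
truncating just over half the protein. They are stand-ins with the
correct arithmetic, not the real mRNA sequences.

## Segregation

"Perfect association" for a fully penetrant recessive variant is a
pattern, not a test: every case homozygous-alternate, no control in any
group homozygous-alternate; the module counts violations rather than
attaching a p-value. Carrier frequency is the heterozygote fraction among
successfully genotyped members of a group (failed assays never enter a
denominator) and is reported to one decimal in percent. Two-locus LD is
the squared Pearson correlation of 0/1/2 dosage vectors over samples
called at both loci; a locus monomorphic among complete pairs makes r²
undefined (an error), not zero.

## Synthetic-data generator

`SimConfig` defaults are the emulated study conditions: 7 cases, 7
controls, 5,000 markers uniformly placed on one 80-Mb chromosome
(≈ 220 markers in the planted segment), a 3,534,378-bp IBD segment,
alternate-allele frequencies 0.05–0.5 (Beta(1.2, 2.0)-shaped, so the
alternate allele is the population-minor allele), 2% missingness, 10⁻³
per-call genotype error, a 12-genome panel, 60 interval plus 600
background variants, and validation cohorts of 200 breed controls
(planted carrier fraction 6.2%) and 357 other-breed dogs with a 2% assay
failure rate. The marker scale keeps the full pipeline with a
10,000-permutation scan in the minutes range on one CPU while preserving
a segment-to-genome marker ratio similar to a real array.

Controls are drawn under per-marker Hardy–Weinberg equilibrium; cases
likewise, except inside the planted segment, where all cases are
homozygous for one founder haplotype (allele drawn by its population
frequency). Errors are modelled as cluster-assignment miscalls — an
errored call is redrawn from the marker's HWE genotype distribution —
then missingness is applied. All noise draws are consumed unconditionally
from the random stream, so a zero-noise run with the same seed is the
exact noise-free twin of a noisy run. QC statistics for passing variants
are drawn comfortably inside every threshold; `fail_fraction` of the
non-planted variants are pushed across each filter family's threshold
(cluster failures fabricate two extra SNV neighbours within 10 bp). The
planted causal deletion and passenger SNV receive clean statistics by
construction — they represent well-supported real calls. The panel
carries every variant except the planted pair and two synonymous
in-interval variants, mirroring the observation that only a few interval
variants are private to the affected breed.

What the generator does *not* emulate: linkage disequilibrium between
background markers, recombination and coalescent structure, breed
demography, allele-frequency spectra from real ascertainment, read-level
sequencing artefacts, or correlated genotyping error. Passing tests on
this substrate therefore demonstrate correctness of the inference chain
under its stated model, not robustness to every failure mode of real
array or sequencing data.

## Determinism and numerics

Every stochastic component takes an explicit seed; the pipeline's
outputs, including the simulated input bundle, are byte-identical across
reruns of one configuration, and `summary.json` carries the seed plus a
SHA-256 configuration hash. Tie-breaks are fixed and documented: marker
sort is (chromosome, position, id); allele-coding ties make the
lexicographically greater allele the alternate; the longest run wins
interval selection (first on ties); Mb rounding is half-up.
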