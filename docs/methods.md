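# Methods

## The problem

Given per-sample small-variant calls (SNPs and short insertions/deletions)
for a cohort of in-group animals, one outgroup animal of the reference-like
breed, and catalogs of already-known variants, the workflow isolates
*breed-specific* variants — present in every in-group sample, absent from
the outgroup and from the catalogs — and then interrogates them three ways:
where they fall in the genome, what they do to a candidate gene's protein,
and whether one of them works as a species-identification marker in a
digital-PCR assay.

## Variant identity and the specificity filter

The atomic identity is the allele-aware key (chrom, 1-based pos, ref, alt).
Multi-allelic VCF records are split into one call per alternate allele in
the genotype; a split record with genotype 1/2 contributes two heterozygous
calls.  Genotype 1/1 is homozygous-alt; any mixed genotype is heterozygous;
phasing is ignored.  MNVs (equal multi-base allele lengths) are rejected
rather than silently misclassified.  The FILTER column is ignored by
default (a `pass_only` flag exists) because the upstream caller's filter
policy is not part of this workflow's contract.

The filter itself is pure set algebra, in three passes with recorded
provenance: (1) intersection of all in-group key sets, keeping each
sample's zygosity; (2) subtraction of the outgroup's keys; (3) subtraction
of catalog keys, allele-aware by default with a position-only mode (which
of the two the original database comparison used is not documented; both
are provided and the default is the stricter one).  Indel keys are
compared literally, with no left-normalisation, on the assumption that all
inputs came from the same caller against the same reference.  Zygosity
enters only at the end: a surviving variant is homozygous-class iff every
in-group sample carries it homozygous.  Per-variant-type counts are
monotonically non-increasing across stages by construction, and on
synthetic cohorts the filter must reproduce the generator's planted truth
exactly — that identity, plus equivalence with a one-shot set expression on
random cohorts, is the filter's correctness argument, since the original
genome-scale inputs are not deposited.

## Region annotation

A deliberately small SnpEff-like classifier with eight classes and a fixed
severity precedence:

SPLICE_SITE > UTR5 > UTR3 > EXON > INTRON > UPSTREAM > INTRAGENIC > INTERGENIC

Choices the class definitions need (none of which the original workflow
documents, so they are fixed here for determinism): splice sites are the
first/last 2 intronic bases of each intron; EXON means coding exon, since
UTRs are listed separately; the upstream window is 5,000 bp from the
transcript start, strand-aware; there is no downstream class, so
downstream positions are intergenic; intragenic means inside a gene span
but in no transcript of that gene.  Across overlapping transcripts the
most severe class wins, giving each variant exactly one label, so region
tallies always partition the input set.

## Coding effects

Two aligned, gap-free, in-frame CDSs are compared codon by codon with the
standard genetic code (the gene of interest is nuclear).  A codon with
several nucleotide differences yields a single record — ref codon vs alt
codon as wholes — matching the one-row-per-residue format of published
substitution tables.  Records carry exon labels (from CDS-offset exon
breaks) and protein-domain labels (from amino-acid intervals).  For the
packaged eqCD1a6 substitution fixture, the domain of each record follows
the stated exon/domain correspondence (six exons encoding signal peptide,
α-1, α-2, α-3, transmembrane, cytoplasmic tail); exact residue boundaries
of the domains are not published, so domain maps are configurable.

## NG86 dN/dS and the sliding window

Sites: for each codon position, the synonymous fraction is the share of
synonymous changes among the three single-base mutants, *excluding mutants
that create stop codons from the denominator*; s is the sum over the three
positions and n = 3 − s, so N + S = 3 per codon exactly (for the default
135 bp window: N + S = 135).  Sites for a codon pair are averaged between
the two codons.

Differences: for a codon pair differing at k positions, the k! substitution
orderings are enumerated; each step is classified synonymous or
nonsynonymous; orderings passing through a stop codon are discarded and the
remainder averaged, so Nd + Sd = k.  In the rare case that *every* ordering
is blocked by a stop intermediate, the blocked orderings are used with
stop-passing steps counted as nonsynonymous — a totality fallback chosen
over raising, documented here because the convention is not standardised.
Correctness is established against an independent exhaustive pathway
enumerator over all ~3.7k valid codon pairs (agreement to 1e−12).

Proportions pN = Nd/N and pS = Sd/S are corrected for multiple hits with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), which is undefined at p ≥ 3/4
(saturation raises; a saturated window reports class *undefined*).  The
window ratio is dN/dS; |ratio − 1| ≤ 0.05 classifies as neutral (the
tolerance is configurable and purely presentational), below purifying,
above positive.  Windows with dS = 0 report the ratio as NaN/undefined
rather than infinity and must be excluded from summary means.  Windows are
codon-aligned by construction, start at base 1 and slide while the full
window fits; the published scan's conventions (window 135 bp, step 9 bp)
are the defaults.  The original scan used a program whose internal
conventions are undocumented; NG86 with equal pathway weighting,
stop-pathway exclusion and Jukes–Cantor correction is implemented as the
canonical reading, and is recorded here so results remain reproducible
even if that program differed.

## Digital PCR

Per channel, λ = −ln((valid − positive)/valid) is the mean template copies
per well; concentration is λ divided by the per-well partition volume.
The instrument's partition volume is not published: the default constant
(1.1468 × 10⁻⁴ µL) is calibrated once, by least squares through the origin
over the 24 nonzero (λ, concentration) pairs of the packaged panel, via
`calibrate_partition_volume`; with it, every printed concentration is
reproduced within 1%.

Calling rule: a channel is *present* when its positive wells reach a
threshold (default 10 — in the packaged panel presences are ≥ 227 and
absences exactly 0, so any threshold in between reproduces the published
calls; 10 guards against isolated false-positive wells).  Channel 1 only →
in-group allele; channel 2 only → outgroup allele; both → heterozygote,
with the λ-ratio attached and flagged when outside [0.5, 2.0] (all four
published heterozygote ratios, 0.87–1.01, fall inside); neither → no call.
A both-present-but-out-of-band sample still calls heterozygote with the QC
flag, because the vendor software's rule is unknown.  Panel accuracy counts
heterozygote and no-call as non-matching; on the packaged panel this
reproduces 16/20 = 80%, which is also how the published accuracy figure is
reconstructed.  The simulator draws each channel's positives binomially
with p = 1 − exp(−conc·volume); the estimator round-trip is unbiased to
< 1% relative at λ ≈ 0.035 (the panel's regime).

## QC arithmetic

Summary-table audits only: clean % = clean/total reads, mapped % =
mapped/clean reads, group means of fold coverage — all half-up rounded
(2 decimals for percentages), which reproduces every derivable percentage
cell of the packaged mapping table.  No reads or alignments are touched.

## Synthetic data: what it emulates and what it does not

All generators take one explicit seed and use no global random state.

*Toy genome*: genes alternate strands along one chromosome, each with a
three-exon transcript, 30 bp UTRs at both ends and a CDS length divisible
by 3; intergenic spacing defaults to 6 kb so upstream windows and true
intergenic sequence both exist.  Sequence content is uniform random —
fine for coordinate arithmetic, meaningless for motif- or GC-dependent
questions.

*Cohort*: each in-group sample carries a planted shared fraction
(default 30% of 1,000 variants; an 80/10/10 SNP/INS/DEL mix) plus private
variants at positions no other sample uses, so the in-group intersection
is exactly the planted set.  Defaults for the overlap knobs (40% of shared
in the outgroup, 50% of the remainder in catalogs) are round mid-range
values chosen once so that every filter stage removes something.
Per-sample homozygosity is an independent Bernoulli (p = 0.35, matching
the per-sample homozygous fraction of the packaged variant tallies); note
this makes *cohort-wide* homozygous variants rare (0.35⁵), unlike real
breed-fixed variants, which are correlated across animals — the truth
bookkeeping, not a marginal rate, is what tests assert.  No linkage,
mutation-rate heterogeneity or coalescent structure is simulated, so a
green filter test establishes set-algebra correctness, not population
genetics realism.

*Coding-pair evolver*: single-base changes proposed uniformly; stop-
creating proposals rejected; for ω ≤ 1 nonsynonymous proposals accepted
with probability ω (synonymous always), for ω > 1 synonymous accepted with
probability 1/ω (nonsynonymous always); proposals continue until the
target substitution count (default 0.15 per codon — enough divergence for
window signal, low enough that multiple hits stay uncommon) is fixed on
one copy.  Realized counts are recorded as truth.  Whole-gene NG86
estimates recover the rank order of ω ∈ {0.2, 1, 5}, and the ω = 1 case
averages inside [0.8, 1.25] over 50 seeds; estimates at large ω are
upward-biased and noisy because synonymous counts are then small and the
ratio is convex in them — rank order, not the value, is the tested claim.

## Numerical and degenerate-input choices

* Percent/ratio report rounding is half-up (2 decimals), matching the
  packaged tables' formatting.
* `poisson_lambda(0, n)` returns exactly 0.0; all-positive wells raise a
  saturation error rather than returning infinity.
* Catalog subtraction with an empty catalog list is the identity; mixed
  allele/position catalog modes are rejected rather than coerced.
* Variant keys are uppercased on construction; ref = alt, empty alleles
  and pos < 1 are rejected at the type boundary so set algebra never sees
  degenerate keys.

## Known limitations

* No genotype likelihoods, phasing, structural variants, MNVs or indel
  left-normalisation.
* The region annotator has no downstream class and no canonical-transcript
  logic beyond the severity precedence.
* dN/dS is pairwise counting only — no maximum-likelihood codon models, no
  among-site rate variation, no multiple-sequence support.
* dPCR modelling starts from well counts; fluorescence clustering into
  positive/negative wells is taken as given, and only two channels are
  supported.
* The QC module audits summary tables; it computes nothing from reads.
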