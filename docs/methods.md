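# Methods

This note documents the models, conventions and numerical choices behind
`hapmeth`, and what the synthetic-study generator does and does not emulate.

## Coordinates and naming

Genomic positions are 1-based inclusive (`chr14:104,060,285–104,060,422`
spans 138 bp); internal amplicon offsets are 0-based half-open, with
converters on `AmpliconReference`. Cytosines are named
`<context><serial>_<last-5-coordinate-digits>` (e.g. `CpG9_60054`), serials
counted per context in coordinate order across both strands.

## The synthetic study

The generator emulates a targeted long-read bisulfite amplicon experiment
end to end, so every downstream module can be tested for parameter
recovery against a molecule-level truth table.

**Packaged amplicon.** `fr_apopt1_klc1_like()` builds a deterministic
900 bp reference (filler sequence from a frozen seed; all functional
positions pinned) carrying seven markers — two indels and five SNPs — that
define three haplotypes, `ADAGAGD`, `ADAGAGI` and the risk haplotype
`TIGACAI`. CpG-SNPs are modelled as variants at the G of the dinucleotide
(or indels inserting/removing it): the cytosine itself survives on every
haplotype but switches context between CpG and CpH, which is what lets a
"destroyed" CpG still show a measurable near-zero M on the risk haplotype.
A C/T variant at the cytosine itself — the case that genuinely erases or
confounds the site — is exercised separately in the masking tests.

**Truth profile.** `data/asm_truth_profile.tsv` pins the per-haplotype mean M of
twenty haplotype-specific cytosines (facilitated CpGs near the lead SNP,
obligatory CpG-SNP effects, and low-level CpH ASM). Unlisted CpGs default
to M = 0.90 and unlisted CpHs to M = 0.004; the minus-strand partner of a
pinned CpG inherits its value (CpG methylation is symmetric), while CpH
truth stays strand-specific.

**Cohort.** Genotypes are two independent haplotype draws (Hardy–Weinberg)
from default frequencies (0.40, 0.30, 0.30) — chosen as a plausible common-
haplotype spectrum; only carrier counts, not population frequencies, are
identifiable from the study design being emulated. Cognitive T-scores are
Normal(38.66, 6.53) for cases and Normal(49.63, 5.04) for controls; age
~ Normal(27, 6.8) clipped to 18–45 and sex are balanced across groups;
smoking is yes/no with rates 0.34/0.29 and 10 % unknown.

**Reads.** Per molecule: haplotype uniform between the subject's two,
bisulfite strand OT/OB with probability ½, per-cytosine methylation
Bernoulli(true M) on the template strand, conversion of unmethylated C with
probability 0.995 (per-molecule total failure at rate 0.01 retains every
C), substitution sequencing error at 0.002/base (CCS-like; indel errors are
omitted — the aligner's indel handling is tested with injected indels
instead), PCR duplication at 0.1 (byte-identical copy of an earlier
molecule's read), 40 reads per subject, constant Q40 qualities with an
injectable low-quality fraction. OB molecules are emitted in plus
orientation, so template conversion appears as G→A. Barcode pairs are
assigned per subject from the 8 × 12 catalog; more than 96 subjects per run
is an error. Reads/molecules are emitted in a fixed order from one
`numpy` Generator, so identical parameters and seed give byte-identical
FASTQ and truth tables.

**What the simulator does not emulate.** Neighbouring cytosines are drawn
independently given the haplotype, so cross-subject correlation between
sites arises only through genotype. Real bisulfite data carry strong
within-molecule co-methylation, cell-type mixtures, coverage waves and
chimeric reads; passing tests here demonstrates correctness of the
pipeline's accounting, not robustness to those phenomena. One visible
consequence: the EBIC-selected network on the simulated ASM set is very
sparse or empty at n ≈ 95 and γ = 0.5, although the estimator recovers
planted structure cleanly at reference settings (see below).

**Melt curves.** Two-state model per allele:
F(T) = 1/(1 + exp((T − Tm)/s)) with Tm = Tm₀ + ΔTm · (methylated fraction),
a genotype's curve being the equal mixture of its two alleles plus optional
Gaussian noise. Defaults Tm₀ = 75 °C, ΔTm = 5 °C, s = 1.5 °C on a
60–95 °C grid at 0.25 °C — representative of small bisulfite amplicons
where full methylation shifts melting by a few degrees.

## Read preparation

Demultiplexing requires an exact match of the forward barcode (read
prefix) and reverse barcode (reverse complement of the read suffix); no
error tolerance, no reverse-complement rescue unless enabled. Read-level
quality is mean per-base error probability converted back to Phred; the
gate keeps reads at exactly Q30 ("no less than"). Duplicates are defined
as byte-identical inserts within a sample — for fixed amplicons a
coordinate-based key carries no information — and the survivor is the
highest-quality read, ties to the smallest read id (idempotent).

## Conversion-aware alignment

Each read is aligned globally (Gotoh affine-gap DP, numba-compiled) to its
known amplicon reference twice: under the OT model reference C vs read T
scores as a match, under OB reference G vs read A; the higher-scoring
strand is kept (tie → OT), which doubles as bisulfite-strand inference.
Scoring: match +2, conversion-consistent +2, mismatch −3; opening a gap
costs −7 (open −6 + extend −1) and each further gapped base −1. Alignment
identity counts conversion-consistent columns as matches; reads below 0.9
identity or shorter than 50 bp are rejected. Equivalence is claimed (and
tested) against an exhaustive pure-python DP oracle, not against any
external mapper.

Per-site states come from the read base at the site's reference column on
the informative strand only (plus-strand cytosines on OT reads, minus on
OB): C→unconverted, T→converted (G/A for OB), other→mismatch, gap or wrong
strand→missing. Marker observations are collected over an anchored window
(one reference base each side of the allele span, insertions included), so
indel alleles resolve by window length and substitution alleles by the
conversion truth table.

The under-conversion filter computes the unconverted fraction over covered
reference-context CpH sites and keeps a molecule iff it is strictly below
5 %. Genuinely methylated CpHs (and risk-created CpGs that are CpH in the
reference frame) inflate the fraction by ~1–2 %, safely below threshold;
molecules covering no CpH are kept with a flag.

## Haplotyping

A read's resolved alleles (ambiguous/missing excluded) are compared with
every catalog haplotype; assignment requires exactly one fully compatible
haplotype and ≥ 2 informative markers (1-marker assignment only by
configuration). Wrong assignments across haplotypes separated by ≥ 3
informative markers would need three coordinated misreads and do not occur;
haplotype pairs separated by a single marker (the two ADAGAG* haplotypes)
can flip on one unlucky error at that marker, which bounds per-read
accuracy near 99.5 % rather than 100 % under default error. Genotypes are
the two best-supported haplotypes; a subject is analysable iff each carried
haplotype has ≥ 5 assigned reads (per bisulfite strand if requested — the
stricter reading of the depth rule; both are supported because the source
description is ambiguous). Homozygotes are retained in group-level
summaries and excluded from within-subject contrasts.

## Methylation calling

Counts pool per (subject, haplotype, site); records below 5× depth, and
(haplotype, site) pairs whose cytosine is absent or genotype-confounded,
are *absent* rather than zero. Per-site M uses the site's own strand only;
site classes: unmethylated (mean M ≤ 1 %), intermediate (20 % < M < 80 %),
hypermethylated (> 80 %), low otherwise; association testing uses
1 % < mean M < 99 %. Allele-averaged subject values average the two
haplotype records of a heterozygote (missing if either is masked or
under-covered) and pass through a homozygote's single value.

## Statistics

All tests are two-sided. Rank tests use tie-corrected asymptotic
approximations without continuity correction, making the two-group
Kruskal–Wallis agree with the Mann–Whitney U to numerical precision;
fully degenerate inputs return H = 0, p = 1. The post-hoc contrast is risk
haplotype vs pooled others. Logistic models are
diagnosis ~ M + age + sex + haplotype dosage (counts of each non-reference
haplotype; the diplotype coding is not identifiable from the source
description), fitted by IRLS with separation/non-convergence flagged
rather than reported. Matched pairs are built greedily in a seeded random
case order, each case taking the unused control with identical unordered
genotype and minimal |coverage difference| (ties to the smallest id); an
exhaustive matching oracle backs the tests. Cognition models are OLS of
the T-score on genotype (full-diplotype factor or 0/1/2 risk dosage) or a
site's allele-averaged M, adjusted for age, sex and diagnosis. BH-FDR is
applied per test family (fragment × test type by default) at α = 0.05.
`pooled_t_from_summary` reproduces the two-sample t from summary
statistics alone (e.g. |t| = 11.32 for the default cognition parameters).

## Structure analysis

Columns are first mapped to normal scores Φ⁻¹(rank/(n+1)) (average ties;
constant columns dropped). Parallel analysis retains eigenvalues exceeding
the 95th percentile of 1000 (500 in the pipeline) same-shape Gaussian
datasets, counting from the top. Factor extraction is maximum likelihood
(EM on standardized data), rotated varimax then promax with κ = 4; the
rotation and the (U'U)⁻¹ factor-correlation convention follow the classic
procedure, with each factor signed so its largest loading is positive.
The network estimator solves the graphical lasso along 100 log-spaced
penalties from the largest absolute correlation down to 1 % of it and
selects by EBIC = −2·loglik + E·log n + 4·E·γ·log p with γ = 0.5; edges
are standardized partial correlations −ω_ij/√(ω_ii ω_jj). Pairwise-complete
correlations require ≥ 20 overlapping subjects per pair; offending columns
are dropped iteratively, and a non-positive-definite matrix is
ridge-repaired with a warning. Reference behaviour: zero edges on
independent Gaussian columns, a single 0.90 ± 0.05 edge for two columns
with r = 0.9 at n = 500, edge count non-increasing in γ, and F1 ≥ 0.8
recovery of a planted sparse precision (p = 15, n = 500).

## MS-HRM

Curves are normalized linearly between the means of a pre-melt and a
post-melt window (defaults: first/last 2 °C — the instrument's proprietary
algorithm is not reproduced, only this stated convention). The difference
statistic is evaluated at t*, the grid temperature maximizing
|unmethylated − methylated standard| (ties to the lowest temperature),
as sample − unmethylated standard; replicate wells are averaged first.
Genotype groups are compared with the same Mann–Whitney routine as the
sequencing statistics.

## Problem sizes and determinism

The packaged study runs 96 subjects × 40 reads (≈ 3,800 alignments of
~900 bp reads, 1–2 minutes on one CPU), giving ≈ 45–50 analysable carriers
per haplotype and ~9× informative depth per (subject, haplotype, site) —
at that depth a cohort-mean M has a standard error near 0.02, which sets
the recovery tolerances used in the tests. All pipeline randomness derives
from a single root seed via spawned `SeedSequence`s; identical config and
seed reproduce every artifact bit-for-bit, and the output manifest records
the seed and SHA-256 of each file.

## Known limitations

No chimeric-read or mapping-quality modelling; no cell-type
deconvolution; no indel sequencing errors in the simulator; no claim of
equivalence with any external aligner or GUI statistics package beyond the
formulas stated here; melt-curve normalization is a convention, not an
instrument reproduction.
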