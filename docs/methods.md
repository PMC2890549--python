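# Methods

## The ASE measurement model

A transcribed marker SNP in a heterozygous subject distinguishes the two
alleles' transcripts. The assay reports one fluorescence peak area per
allele, from cDNA and from genomic DNA. The per-replicate statistic is the
cDNA common/rare area ratio normalised by the gDNA common/rare ratio; gDNA
comes from a balanced 1:1 template, so its ratio estimates the assay's
allele-specific amplification bias and dividing by it cancels that bias.
"Common" is defined per SNP as the allele with the higher frequency among
the cohort's genotypes, ties broken toward the lexicographically smaller
allele symbol (the reference population for "common" is otherwise
arbitrary; this choice is deterministic and reproducible from the data).

Replicates follow the assay design: two independent cDNA preparations, each
in duplicate, giving four ratios whose arithmetic mean is the subject's
per-SNP ASE value. Fewer than four ratios are averaged anyway (n ≥ 1) with
a warning. Each cDNA replicate slot is normalised by the gDNA measurement
in the same (prep, duplicate) slot when one exists; otherwise all cDNA
slots share the mean gDNA ratio. Both pairings are consistent with how such
assays are run; the per-slot form is the default and a single shared gDNA
ratio is available via the simulator's `shared_gdna` flag.

**Diagnostic band.** A subject is ASE-positive when the mean ratio is
≥ 1.5 or ≤ 0.67, boundaries inclusive (a strict-inequality mode exists).
The band is deliberately not reciprocal: 1/1.5 = 0.666… ≤ 0.67 is positive.
Subjects heterozygous at several markers are called positive if **any**
informative SNP passes; per-SNP ratios are reported and a `concordant` flag
is cleared when two informative SNPs disagree in direction (one ≥ 1.5 and
another ≤ 0.67). Ratios are not averaged across SNPs because the
common/rare orientation is not phase-consistent between markers.
Subjects with no heterozygous marker are uninformative and are excluded
from the phenotype groups used downstream.

## Haplotype frequencies and LD

Two-locus haplotype frequencies are estimated from unphased 0/1/2 genotype
codes by EM under Hardy–Weinberg. Only subjects heterozygous at both loci
are phase-ambiguous; the E-step splits them between the coupling and
repulsion configurations in proportion to current frequency products.
Numerical choices: convergence when the largest frequency change is below
1e-10, at most 1000 iterations, pairwise-complete subjects only. The
linkage-equilibrium product of observed allele frequencies is itself an EM
fixed point (a saddle of the likelihood) on some datasets, so three
deterministic starts are run — the equilibrium product and two versions
exponentially tilted toward/away from the observed genotype covariances —
and the highest final observed-data log-likelihood wins. There are no
random restarts; results are fully reproducible. The observed-data
log-likelihood is recorded every iteration and is non-decreasing by
construction.

From the frequencies: `D = p11 − pA·pB`; `r² = D²/(pA qA pB qB)`, clipped
to [0, 1] against float error; `D′ = D/Dmax` with the standard
sign-dependent `Dmax`. A monomorphic locus leaves r² explicitly undefined
(`None`), never silently 0.

## Tag selection

"Common SNP" means MAF ≥ 0.05 (a HapMap-era convention; configurable — the
choice of cutoff is a design decision, not an estimate). Greedy selection
repeatedly promotes the SNP that covers (r² > 0.8) the most still-uncovered
common SNPs, ties resolved toward higher MAF and then input order. Before
each promotion, every uncovered SNP is offered **two-tag haplotype rescue**:
three-locus haplotype frequencies (direct counting when phased haplotypes
are supplied, an 8-haplotype EM otherwise) define pseudo-markers — each of
the four tag-allele pairs plus the three two-vs-two groupings of them — and
the best pseudo-marker r² against the target allele is used. Including the
groupings means a target identical to a tag scores r² = 1, as it should.
An exhaustive minimum-cardinality search is available for panels of ≤ 15
common SNPs. Coverage is summarised as the mean best-proxy r² over common
SNPs (tags contribute 1) and the count covered at threshold.

## Association

Each SNP is tested with an allelic 2×2 table (two alleles per subject;
dominant/carrier coding behind a flag), an uncorrected Pearson chi-square
with df = 1, and the cross-product odds ratio, printed as the literal
`n/a` when a zero cell leaves it undefined (Haldane–Anscombe +0.5 behind a
flag). Missing genotypes drop the subject for that SNP only. No
multiple-testing adjustment is applied by default; p-values are reported
raw across the panel. Hardy–Weinberg equilibrium is neither assumed nor
tested — the allelic test's validity rests on it, which is a documented
caveat rather than a checked condition. Clinical 2×2 contrasts (e.g. colon
vs rectum by ASE status, stage IV vs the rest) use a two-sided Fisher
exact test under the probability-mass rule: the p-value sums hypergeometric
probabilities over all tables with the observed margins that are no more
probable than the observed table, with a 1e-9 relative tolerance guarding
ties against float noise. `odds_ratio_from_freqs` reconstructs an allelic
OR from two groups' reported allele frequencies alone, for comparing
against published tables whose underlying counts are unavailable.

## The synthetic cohort

The generator emulates the data structure the analysis assumes, not any
particular patient population:

- **Haplotype pool.** LD arises only from an explicit pool built as the
  cross product of independent blocks (no recombination or coalescent
  model). The default 23-SNP panel plants a causal allele at frequency
  0.10 on a haplotype that also carries a perfect proxy (r² = 1) and a
  partial proxy (r² ≈ 0.63), and puts the four assay markers in two
  internally perfect blocks with MAF 0.28 and 0.12. Under Hardy–Weinberg
  these defaults give an exact noise-free ASE prevalence of 9.5%
  (`expected_prevalence` computes it by enumerating haplotype pairs) and
  ~53% informative subjects.
- **Expression.** Every haplotype expresses at 1.0, multiplied by
  `effect_fold` (default 0.5) when it carries the causal allele. A
  heterozygous carrier therefore shows a 2-fold allelic imbalance; a
  homozygous carrier is reduced but balanced — invisible to the assay by
  design.
- **Noise.** Each peak area is multiplied by lognormal(0, σ) noise:
  σ_cDNA = 0.10, σ_gDNA = 0.05 by default. The platform's true noise
  magnitude is not published; these are calibration choices giving a
  comfortable margin between the 2-fold signal (|log R| = 0.69) and the
  call threshold (log 1.5 = 0.41) — about 3.6 SD for the 4-replicate mean,
  so sensitivity ≈ 1 and false positives are negligible at defaults.
  Power degrades as `effect_fold → 1`, which the sensitivity-monotonicity
  test exercises.
- **Covariates** (sex, ethnicity, tumor location, stage, family history,
  age) are drawn independently of ASE status — the null clinical design —
  with category probabilities matching the reference cohort's margins.
- **Seeds.** One master seed; child streams for subject draws, peak noise
  and covariates are spawned deterministically, so identical configs give
  byte-identical output files.

What passing simulation tests does **not** show: real assays have
prep-level correlated noise, allele-specific dropout, and population
structure none of which the generator models; recovery results here bound
behaviour under the stated noise model only.

## Fixtures and problem sizes

The bundled demographic fixture (`datasets.demo_cohort`) is a synthetic
reconstruction of a published 118-subject cohort summary: per-subject rows
are an arbitrary arrangement consistent with the published stratified
counts (11 ASE-positive, 74 informative, 6 of 11 positives carrying the
9A/6A allele), not patient data. Simulation-based tests use 100–200
cohorts of 118 subjects (and one 800-subject cohort per point for the
sensitivity grid), sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances while the full suite runs in under two minutes.

## Known limitations

- The allelic association test ignores covariates; no logistic regression
  or stratification correction (out of scope).
- The EM handles two and three loci only — exactly what pairwise LD and
  two-tag rescue need — not general phasing.
- Read-count (sequencing) ASE is out of scope; the input is always a pair
  of peak areas.
- Published odds ratios reconstructed from two-decimal frequencies carry
  the rounding slack of their inputs (≲3% relative); exact recovery would
  require the unpublished per-SNP denominators.
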