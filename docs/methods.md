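# Methods

## Generative model

A transcript of length L carries m divergent sites at which a second gene
copy (the "Y-linked" allele in the PAR2 setting) differs from the
reference sequence. Each sequenced read originates from the second allele
with probability f — the bulk reactivation fraction, i.e. the fraction of
the gene's transcripts produced by the normally silenced copy — and from
the reference-bearing allele otherwise. Each base miscalls with
probability ε, substituting uniformly among the three other bases (ε/3
each). The reference-read probability at a position is therefore

    p_ref = (1 − f)(1 − ε) + f·ε/3     at a divergent site
    p_ref = 1 − ε                      elsewhere

and per-position base counts are multinomial draws in these probabilities,
so the reference count is marginally binomial in p_ref. f = 0 reproduces
silencing (hom-ref appearance), f = 0.5 balanced biallelic expression,
f = 1 pure second-allele expression. A cell-mixture reading — a fraction
of cells reactivated times a within-cell allelic fraction — collapses to
the same bulk f and is not separately parameterized.

By default the reference base sits on the X-linked (active) allele, so
silencing looks hom-ref; the assignment is configurable since nothing
forces the active copy to match RefSeq. The reference sequence itself is
derived deterministically from the gene name and length, so scenarios
sharing a transcript agree on it regardless of their sampling seeds.

**Depth law.** Two modes: a fixed per-position depth (unit testing), or a
total-mapped-read law in which the per-transcript read total is drawn
uniformly from a configurable range — default 653–4033, a realistic range
for a moderately expressed transcript in a bulk brain RNA-seq library —
and reads of fixed length (default 100 nt) are placed uniformly along the
transcript. Per-position coverage is then ≈ total·read_length/L. Spreading
single-position "reads" instead would leave sub-1× coverage over a
multi-kb transcript and make per-coordinate genotyping impossible, so
reads have extent. Realized read totals always lie inside the configured
range; zero-coverage positions are simply absent from the pileup (never
imputed).

**Sexes.** At a pseudoautosomal gene a female sample is genuinely
heterozygous at the divergent sites irrespective of f: her two expressed
alleles are modeled at 50:50. This provides the within-study positive
control for the het signature.

**What the generator does not emulate:** alignment and mapping bias
(inputs are taken as uniquely mapped), indels and strand effects,
position-dependent error profiles, overdispersion from PCR duplicates,
and RNA editing. Passing tests therefore demonstrate the statistical
machinery under a clean binomial/multinomial error model, not robustness
to alignment artifacts — on real data the artifact-flagging stage and the
outlier exclusion in noise calibration are the (partial) defenses.

## Classification

Counts are collapsed to reference vs non-reference; the three genotype
classes have reference-match probabilities 1 − ε, ½(1 − ε) + ½·ε/3 and
ε/3, reducing to the idealized {1, 0.5, 0} at ε = 0. Log-likelihoods are
binomial; posteriors are computed in log space with max-subtraction
(log-sum-exp) and default uniform priors. The ε/3 hom-alt probability
(a genuine miscall back to the reference) makes the model slightly
asymmetric under ref/alt exchange for ε > 0; exact label symmetry holds
at ε = 0 and is tested there.

Calls require depth ≥ d_min and winning posterior ≥ τ; defaults d_min = 20
and τ = 0.95 are chosen so that a handful of miscalls at typical depths
cannot manufacture a het call (at ε = 0.01, d = 60, a het call needs
k ≤ ~50 of 60 reference reads — around ten mismatches — which has
probability ~10⁻⁹ under hom-ref). Both gates are configurable and
CLI-exposed; they stand in for whatever upstream quality filtering a real
pileup pipeline applied. ε < 0.75 is enforced: beyond it the hom-ref and
het classes exchange order and the model is unidentifiable.

Noise calibration pools counts per position across samples of the
negative-control gene, drops positions whose pooled non-reference
fraction exceeds 0.2 (default; plausible germline variants or RNA-editing
sites rather than noise), and takes ε̂ as pooled mismatches over pooled
depth. The binomial standard error √(ε(1−ε)/pooled depth) quantifies its
precision.

## Artifact flagging

"Recurrently inconsistent" positions are excluded from heterozygote
counts. Default rule: a position is flagged when, within each cohort
separately, the non-missing calls span all three genotype classes — a
pattern incompatible with any true genotype configuration but typical of
context-specific mis-alignment. The stricter alternative flags positions
where ≥ 50 % (configurable) of called samples in each cohort disagree
with that cohort's modal call. Whether the original inspection-based
screen was algorithmic is unknowable; both rules are declared
operationalizations, and the default was chosen because it is monotone
(removing a sample can never create a flag) and parameter-free.

## Cohort comparison

The test statistic is the difference in mean per-sample het-site burden.
The permutation p-value enumerates all label assignments when
C(n, n₁) ≤ 10⁵ (then p = #{|Δ*| ≥ |Δ|}/total, which includes the identity
and is never 0) and otherwise samples n_perm permutations with the
add-one convention p = (1 + hits)/(n_perm + 1). A Fisher exact test on
the cohort × (any het site) 2×2 table is reported alongside as the
coarser, detection-style comparison. Genes are analyzed separately with
no cross-gene multiplicity adjustment (each gene answers its own
question; the comparison of interest involves a single test gene).
Females are excluded from the male-biallelism test by default — they are
legitimately heterozygous — and retained as positive controls.

Permutation tests on integer burdens are exact but conservative: under a
null where most burdens tie (in the extreme, all zero) the attainable
p-values are coarse and the realized type-I error falls below α. The
null-calibration test therefore checks the one-sided bound (rejection
rate ≤ α plus binomial noise) on an exchangeable null with per-sample
depth variability, rather than demanding a rejection rate centered on α.

## Power analysis

Each grid cell (f, m, depth, n, ε) replays the full pipeline per
replicate: simulate case (fraction f) and control (f = 0) cohorts,
calibrate ε̂ on the monoallelic control cohort (the hemizygous-control
role), classify, flag artifacts, count burdens, permutation-test.
Reported per cell: mean fraction of case samples with ≥ 1 non-flagged het
call, probability that at least one case sample is detected, and the
cohort-level rejection rate, each with binomial standard errors.

Interpretation caveats: detection rests on the ~50:50 het signature, so
f = 0.5 (full reactivation: both alleles at equal output) is the most
detectable state, and power is monotone in f on [0, 0.5]. It is *not*
monotone in depth for small f when ε > 0: at f ≈ 0.1 a shallow pileup
cannot distinguish a 90 % reference fraction from heterozygosity and
(spuriously) calls het, while a deep pileup correctly resolves the site
as neither het nor hom-ref — so the apparent power at low depth for small
f partly reflects model mismatch, and f = 1 (silencing of the *X* copy)
is invisible to a het-based detector. The monotonicity checks in the
acceptance suite accordingly use a zero-error grid over f ∈ [0, 0.5].

## Problem sizes and numerical choices

The analysis scripts use a 1,200-nt transcript (compact stand-in for a
multi-kb transcript; per-position coverage with the 653–4033 read law is
then ~55–335×, comfortably within the regime the classifier assumes) and
the study's cohort sizes (33 + 38 males, one female control). The
null-calibration suite runs 1,000 replicate 20-vs-20 cohorts on a 200-nt
transcript with 25-nt reads and 100–240 total reads so that per-site
depth straddles the d_min gate — that variability is what makes the null
non-degenerate. The acceptance checks use 10,000 depth-100 columns for
the heterozygous-site mean (Monte-Carlo SE ≈ 0.0005).

Ties in the posterior argmax resolve toward hom-ref (first index), which
can only occur at measure-zero parameter coincidences; p = 0 or 1 class
probabilities yield −∞ log-likelihoods handled exactly in log space.
Scenario/seed pairs are bit-reproducible; every output table records its
generating seed where applicable.

## Known limitations

* The binomial model ignores overdispersion; real allelic fractions drift
  with library complexity, so ε̂ and the het posterior are optimistic on
  real data.
* Artifact flagging needs ≥ 2 cohorts by construction; single-cohort
  studies must run without it.
* The divergent-site count m between the X- and Y-linked transcripts of a
  real PAR2 gene is unknown and is a free simulation parameter; all power
  statements are conditional on m.
* Detection is bounded by biology: if reactivation kills the expressing
  cells, no amount of sequencing depth recovers the signal — the power
  surface quantifies only the statistical side of that argument.
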