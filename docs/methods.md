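# Methods

`somascape` implements the cohort-level computational workflow of a
whole-exome pancreatic ductal adenocarcinoma (PDA) study: mutation spectra
and etiology signatures, mutation burden and mutator detection, gene-level
copy number with recurrence and survival scans, pathway (oncoprint)
matrices with correlation and exclusivity statistics, affinity-propagation
subtype discovery, and the survival/enrichment statistics layer. Because
patient-level sequencing data of such studies is access-controlled, the
package ships a synthetic cohort generator whose defaults encode the
published cohort-level figures, so every stage of the pipeline is testable
fully offline.

## Ingest and variant-level filters

Mutations arrive as a MAF-like TSV (1-based inclusive coordinates),
copy-number segments as SEG, clinical covariates as TSV. Gene models are
BED-style 0-based half-open; all conversions are internal and explicit.

The read-depth filters applied at ingest are: SNVs require ≥ 14 reads
covering the site in the tumour and ≥ 8 in the normal; indels additionally
require tumour reference count > 8 and tumour variant count > 3 (strict
inequalities). Two details are underdetermined by the thresholds alone and
are fixed here as package policy, recorded in the ingest metadata:
"reads covering a site" is taken as the ref+alt count sum, and the indel
reference-count condition is applied on the tumour side.

## Mutation spectra

Single-base substitutions are collapsed onto the pyrimidine strand
(purine-reference calls are reverse-complemented together with their
trinucleotide context), yielding the six classes C>A, C>G, C>T, T>A, T>C,
T>G, optionally refined by the 16 flanking-context pairs into the standard
96-channel spectrum (class-major, then 5′ base, then 3′ base). Spectra
include silent mutations: they describe the mutational process, not its
coding consequence. Burden, in contrast, counts only nonsilent
(protein-altering) events — missense, nonsense, splice-site, and
frameshift/in-frame indels.

Context queries (`context_fraction`) accept IUPAC patterns, e.g. the
mismatch-repair-deficiency motif `CTG` for T>C, or the APOBEC target `TCW`.
The APOBEC fold-enrichment score is

    score = [ n(C>T∪C>G at TCW) / n(C>T∪C>G) ] / [ bg(TCW) / bg(C) ]

with `bg` a background trinucleotide frequency table (pyrimidine-collapsed;
`uniform_context_background()` is the correct background for the
generator's position-unconditional draws). The ratio is deliberately
computed **within** the APOBEC substitution classes so that the score is
1-centred under a context-uniform null regardless of how the six classes
are mixed; dividing instead by all C-centred mutations would make the null
value depend on the class composition (2/3 under a fully uniform process).

Group spectrum comparisons use a per-class two-sample pooled-variance
Student's t on per-case fractions (two-sided); a zero-variance comparison
with equal means returns p = 1 by convention. Spectrum clustering is
agglomerative with Euclidean metric and complete linkage — the linkage was
an open choice; complete linkage was chosen for its tendency to produce
compact, balanced clades on probability vectors.

Mutator enrichment tests whether mismatch-repair-type lesions concentrate
in the top burden quartile: the quartile is the ceil(n/4) highest-burden
cases (ties broken by roster order — "top quartile" alone fixes no
rounding or tie rule, so ours is explicit), and the p value is the exact
upper-tail hypergeometric. The significance post-filter keeps genes
with ≥ 4 nonsilent mutations (> 3.5% of 109) and p < 0.05, sorted by p;
the upstream per-gene significance model itself is out of scope and its p
values are an input.

## Affinity propagation

Implemented from the message-update rules, with similarity matrix `s`
(shared preference on the diagonal) and damping λ
(new = λ·old + (1−λ)·computed):

    r(i,k) ← s(i,k) − max_{k′≠k} [ a(i,k′) + s(i,k′) ]
    a(i,k) ← min{0, r(k,k) + Σ_{i′∉{i,k}} max(0, r(i′,k))}   (i ≠ k)
    a(k,k) ← Σ_{i′≠k} max(0, r(i′,k))

`a` is initialized to 0; exemplars are the points with r(k,k)+a(k,k) > 0;
non-exemplars join their highest-similarity exemplar (ties to the lower
index, logged as policy). Convergence is an exemplar set unchanged for
`conv_window` consecutive iterations; if `max_iter` is reached first, the
best state seen (highest net similarity = Σ member→exemplar similarities +
Σ exemplar preferences) is returned with `converged=False`.

Defaults λ = 0.9, max_iter = 1000, conv_window = 50 follow common affinity
propagation practice; the preference defaults to the median of off-diagonal
similarities, which adapts the cluster count to the data. All three are
config-exposed, and cluster *counts* are therefore configuration-dependent
rather than a validated output. An eps-scale deterministic jitter is added
to the similarities before message passing (assignments and net similarity
use the unjittered input): exactly duplicated points otherwise leave the
messages permutation-symmetric and unable to break ties — the same device
reference implementations use.

The hierarchy re-clusters the exemplars by their **original profile rows**
(similarities recomputed among exemplars), repeating while the cluster
count strictly decreases; this reading of "cluster the exemplars together"
keeps every level interpretable in the original feature space.

`exhaustive_exemplar_oracle` maximizes net similarity exactly by brute
force (n ≤ 12) and anchors the tests: on duplicated-point families the
message-passing optimum equals the oracle's, and on random n = 7 similarity
matrices it reaches within 5% of the optimum on ≥ 90% of seeds — a
regression property of this implementation, not a theorem.

## Copy number

Segments are projected to genes by overlap-length-weighted mean log2 ratio
over the gene span; a gene no segment touches is 0 with a coverage flag
(dense matrices cluster better than ones with holes). Calls use the usual
log2 conventions — ±0.3 low-level, ±0.9 high-level — as explicit,
adjustable thresholds, since calling cut-offs are a free parameter of such
pipelines. Per-case complexity is the fraction of genes with non-neutral
calls.

The recurrence scan is a deliberately simplified stand-in for peak-finding
tools of the GISTIC family (whose internals are out of scope): a per-gene
G-score Σ_cases max(0, x − 0.3) for amplifications (mirrored for
deletions) with a null that circularly shifts each case's gene-ordered
profile independently within each chromosome — preserving per-case
amplitude structure while decoupling genomic position. Empirical p values
use the (1+B)/(n_perm+1) convention and are Benjamini-Hochberg-adjusted per
direction. Chromosomes with one modelled gene cannot be shifted and are
reported untested. The scan preserves amplitude×frequency logic but is
*not* equivalent to GISTIC.

The locus–survival scan dichotomizes each locus as altered vs not (any
non-neutral call — the dichotomization threshold is a free parameter),
requires ≥ 2 cases per arm, and reports log-rank p, univariate Cox HR and
BH q per locus.

## Pathways and oncoprints

The gene alteration matrix is binary: 1 iff the case has a nonsilent
mutation in the gene or a qualifying copy-number call; per-type
(mutation/amp/del) sub-matrices are retained. Pathway membership is
configuration, not code: a YAML maps each member gene to its qualifying
alteration types, and the packaged defaults are a documented approximation
of the recurrently altered PDA pathways (exact memberships of the original
study live in supplementary material). A pathway column is the union over
qualifying member alterations; its frequency is the column mean.

Pairwise pathway association uses Pearson correlation on the binary
columns (constant columns excluded with a warning). Mutual exclusivity of
two genes is the exact lower-tail hypergeometric probability of an overlap
at most as large as observed — chosen over permutation for exactness at
cohort scale.

Unsupervised Random-Forest clustering uses the synthetic-contrast
construction: real rows labelled 1, a column-wise permuted copy labelled 0,
a forest trained on the contrast; proximity of two real rows is their
co-leaf frequency and dissimilarity is 1 − proximity. Partitioning around
medoids is the classic build + swap with the total-dissimilarity objective,
fully deterministic given the forest seed.

## Survival and enrichment statistics

Kaplan-Meier and log-rank go through lifelines; the median is the smallest
t with S(t) ≤ 0.5 and is reported as undefined (None) when S never reaches
0.5, never as the largest observed time. The univariate Cox model is fit
directly by Newton-Raphson on the partial likelihood with Breslow tie
handling (simpler than Efron and adequate at cohort scale); a monotone
likelihood — e.g. all events in one covariate arm — is reported as
`converged=False` rather than raised, because scans must survive degenerate
loci. All tests are two-sided. BH q values come from statsmodels.

## The synthetic cohort generator

The generator emulates a post-calling, post-filtering mutation catalog,
CBS-style segment profiles and clinical covariates. What it draws:

* **Drivers.** Each configured gene is an independent Bernoulli at its
  marginal frequency, except mutual-exclusivity groups (KRAS 0.92 /
  BRAF 0.03 / PIK3CA 0.01 in the packaged profile), where a single
  categorical draw picks at most one member per case — so marginals are
  exact and exclusivity is a *hard* constraint, making the power of the
  exclusivity test measurable. Canonical drivers get fixed hotspot lesions
  (e.g. the BRAF V600E substitution); others get signature-drawn lesions
  within their gene-model span.
* **Burden.** Nonsilent count per case from a log-normal (σ_log = 0.5)
  with a latent mutator fraction (3%) carrying a 10× multiplier and a
  forced mismatch-repair gene lesion. The configured `mean_count` (67) is
  the *cohort-wide* expectation — the observed average of such a cohort
  includes its hypermutators — so the base log-normal mean is derived as
  mean/(1−p+p·mult). Passengers fill the burden; silent mutations are
  added at silent fraction 0.25 of all coding events.
* **Spectra.** Trinucleotide contexts are drawn i.i.d. from per-etiology
  96-channel mixtures built from three parametric signatures: ageing-like
  (C>T-dominated, boosted at NpCpG), smoking-like (C>A-dominated), and
  mismatch-repair-like (T>C concentrated at CTG). Smokers draw from
  0.6·smoking + 0.4·ageing, latent mutators from 0.7·MMR + 0.3·ageing.
  The per-etiology weights are free parameters set from qualitative
  descriptions of such spectra; they are documented configuration, not
  measured quantities. Roughly half the SNVs are emitted on the purine
  strand so the pyrimidine collapse is genuinely exercised. Contexts are
  unconditional on genomic position; no reference genome is simulated.
* **Copy number.** Per chromosome, a diploid baseline (noise σ = 0.1 log2,
  split into ~50 Mb chunks) with sampled focal events carved in at the
  configured loci (CDKN2A del 0.41, MYC amp 0.14, SMAD4 del 0.20, CCND1
  amp 0.09; amplitudes ~Normal(±1.2–1.5, 0.15–0.2), ±250 kb flanks).
* **Survival.** Exponential proportional hazards with independent uniform
  censoring (rate 0.30): hazard h0·exp(Σβx) with covariates smoker
  (log-HR ln 2 — smokers' median roughly half of non-smokers'), MYC
  amplification (log-HR ln 1.8) and grade 3 (log-HR ln 1.5). Exponential
  rather than Weibull because only medians and hazard ratios are being
  emulated; it is the minimal PH model. The packaged profile specifies the
  *cohort* median (21 months, the figure such a study reports); at
  generation time the baseline (reference-covariate) hazard is
  back-calculated by inverting the marginal survival mixture over the
  independent covariate distribution, which for the packaged profile gives
  a reference-arm median of ≈ 31.6 months. A profile may instead pin the
  baseline median directly.

Everything flows through a single numpy Generator: a (profile, seed) pair
reproduces the cohort byte for byte.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: subclonality and purity, germline variation,
position-dependent mutation rates and true exome context composition,
correlated driver co-occurrence beyond the exclusivity groups, segment
breakpoint noise around focal events, and non-proportional hazards.

## Problem sizes and numerical choices

Recovery benchmarks use 20 cohorts of 109 cases (the study scale);
large-sample parameter-recovery tests use single cohorts of 2000–4000
cases; null-calibration suites use 1000 simulations with 60–100 subjects
each; the recurrence scan is validated at 500 permutations. These sizes
give 3-SD binomial bounds of 1–3 percentage points on the recovered
frequencies. Newton-Raphson Cox stops at |step| < 1e-9 (max 60 iterations)
and declares divergence past |β| > 20; brentq tolerances are scipy
defaults; empirical p values never report 0 by construction.

## Known limitations

* Cluster counts from affinity propagation depend on preference/damping
  configuration and are not an anchored output.
* The recurrence scan is not GISTIC; q values are comparable in spirit,
  not in value.
* The hypergeometric exclusivity test conditions on both marginal
  alteration counts and ignores per-case mutation-rate heterogeneity,
  which can inflate exclusivity signal in hypermutated cohorts.
* Only univariate Cox models are provided; multivariable adjustment,
  competing risks and interval censoring are out of scope.
* Packaged pathway memberships and the bundled gene model are minimal,
  editable approximations intended for the packaged profiles.
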