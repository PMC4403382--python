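# Default 109-case pancreatic ductal adenocarcinoma cohort profile.
# Alteration frequencies, burden, survival and covariate effects encode the
# published cohort-level figures this generator emulates: KRAS 92%,
# BRAF V600E 3% (mutually exclusive with KRAS), CDKN2A loss 41%, MYC amp
# 14%, SWI/SNF pathway 42%, DNA-repair pathway >35%, FLG 10%, mean
# nonsilent burden 67/case, cohort median survival 21 months, smokers at
# roughly twice the hazard of non-smokers.
n_cases: 109
case_prefix: PDA

histology_probs: {PDA: 0.862, adenosquamous: 0.101, colloid: 0.037}
smoking_probs: {smoker: 0.30, non-smoker: 0.60, unknown: 0.10}
grade_probs: {1: 0.046, 2: 0.706, 3: 0.248}
stage_probs: {I: 0.046, II: 0.890, III: 0.055, IV: 0.009}
node_positive_prob: 0.65

# marginal per-gene nonsilent mutation probabilities (independent draws)
gene_mutation_probs:
  TP53: 0.60
  SMAD4: 0.15
  FLG: 0.10
  GNAS: 0.055
  RNF43: 0.055
  RBM10: 0.037
  IRF6: 0.04
  AXIN1: 0.05
  GLI3: 0.06
  STK11: 0.02
  RB1: 0.02
  CTNNB1: 0.03
  TGFBR1: 0.03
  TGFBR2: 0.04
  ACVR1B: 0.03
  NOTCH1: 0.02
  NOTCH2: 0.02
  # SWI/SNF members: each 1-(1-0.42)^(1/6) so the pathway union is 42%
  ARID1A: 0.0868
  ARID1B: 0.0868
  ARID2: 0.0868
  PBRM1: 0.0868
  SMARCA4: 0.0868
  SMARCA2: 0.0868
  # DNA-repair members: union ~40% (combined DNA-repair lesions >35%)
  FANCA: 0.04
  FANCC: 0.04
  FANCD2: 0.04
  FANCF: 0.04
  FANCG: 0.04
  ATM: 0.08
  CHEK2: 0.06
  BCLAF1: 0.06
  BRCA1: 0.05
  BRCA2: 0.05
  # mismatch repair (independent of the forced latent-mutator lesions)
  MLH1: 0.01
  MSH2: 0.01
  MSH6: 0.01

# at most one member per case; weights are the marginal frequencies
exclusivity_groups:
  - {KRAS: 0.92, BRAF: 0.03, PIK3CA: 0.01}

mutator_genes: [MLH1, MSH2, MSH6]

burden_model:
  mean_count: 67.0        # cohort-wide mean nonsilent mutations per case
  log_sd: 0.5
  mutator_multiplier: 10.0
  mutator_prob: 0.03

silent_fraction: 0.25

signatures:
  aging: builtin
  smoking: builtin
  mmr: builtin

etiology_mixtures:
  baseline: {aging: 1.0}
  smoker: {smoking: 0.6, aging: 0.4}
  mutator: {mmr: 0.7, aging: 0.3}

# focal copy-number events (log2-ratio amplitude ~ Normal(mean, sd))
cnv_loci:
  - {name: CDKN2A, gene: CDKN2A, kind: del, prob: 0.41, mean: -1.3, sd: 0.15}
  - {name: MYC, gene: MYC, kind: amp, prob: 0.14, mean: 1.5, sd: 0.2}
  - {name: SMAD4, gene: SMAD4, kind: del, prob: 0.20, mean: -1.2, sd: 0.15}
  - {name: CCND1, gene: CCND1, kind: amp, prob: 0.09, mean: 1.3, sd: 0.2}

noise_sd: 0.10

survival_model:
  # observed cohort median; the reference-covariate baseline hazard is
  # back-calculated from this given the covariate mix below
  cohort_median_months: 21.0
  log_hr:
    smoker: 0.6931      # HR 2: smokers' median roughly half of non-smokers'
    MYC_amp: 0.5878     # HR 1.8: MYC amplification, poor outcome
    grade3: 0.4055      # HR 1.5: grade 3 disease
  censoring_rate: 0.30
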