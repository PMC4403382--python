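# Default pathway definitions for the oncoprint layer. Each member gene
# lists the alteration types that qualify it (nonsilent mutation,
# amplification, deletion). These memberships are an editable, documented
# approximation of the recurrently altered PDA pathways; supply your own
# YAML for other gene sets.
KRAS_pathway:
  KRAS: [mutation]
  BRAF: [mutation]
  PIK3CA: [mutation]
TP53:
  TP53: [mutation]
RB_pathway:
  CDKN2A: [mutation, del]
  CDKN2B: [del]
  CDK4: [amp]
  CCND1: [amp]
  RB1: [mutation, del]
TGF_beta:
  SMAD4: [mutation, del]
  TGFBR1: [mutation]
  TGFBR2: [mutation]
  ACVR1B: [mutation]
SWI_SNF:
  ARID1A: [mutation]
  ARID1B: [mutation]
  ARID2: [mutation]
  PBRM1: [mutation]
  SMARCA4: [mutation]
  SMARCA2: [mutation]
DNA_repair:
  FANCA: [mutation]
  FANCC: [mutation]
  FANCD2: [mutation]
  FANCF: [mutation]
  FANCG: [mutation]
  ATM: [mutation]
  CHEK2: [mutation]
  BCLAF1: [mutation]
  BRCA1: [mutation]
  BRCA2: [mutation]
Beta_catenin:
  RNF43: [mutation]
  AXIN1: [mutation]
  CTNNB1: [mutation]
Notch:
  NOTCH1: [mutation, amp]
  NOTCH2: [mutation, amp]
Mismatch_repair:
  MLH1: [mutation]
  MSH2: [mutation]
  MSH6: [mutation]
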