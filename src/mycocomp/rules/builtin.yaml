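# Curated domain-architecture rule sets.
#
# Pfam accessions: 7tm_1 PF00001, FRQ PF09421, GATA PF00320, PAS_3 PF08447,
# PAS_9 PF13426, Bac_rhodopsin PF01036, GpcrRhopsn4 PF10192,
# DNA_photolyase PF00875, FAD_binding_7 PF03441, PHY PF00360, GAF PF01590,
# RdRP PF05183, Dicer_dimer PF03368, PAZ PF02170, Piwi PF02171,
# Ribonuclease_3 PF00636, DEAD PF00270, DNA_methylase PF00145.
#
# "exact" encodes expected combination AND frequency (e.g. a WC1 candidate
# carries one each of GATA, PAS_3, PAS_9); "min" is presence at >= count.

circadian:
  FRQ:
    required:
      FRQ: {count: 1, mode: min}
  WC1:
    required:
      GATA: {count: 1, mode: exact}
      PAS_3: {count: 1, mode: exact}
      PAS_9: {count: 1, mode: exact}
  WC2:
    required:
      GATA: {count: 1, mode: exact}
      PAS_3: {count: 1, mode: exact}
    forbidden: [PAS_9]
  Rhodopsin:
    required:
      7tm_1: {count: 1, mode: exact}

rnai:
  RDRP:
    required:
      RdRP: {count: 1, mode: min}
  Dicer:
    required:
      Dicer_dimer: {count: 1, mode: min}
  Ago:
    required:
      PAZ: {count: 1, mode: min}
      Piwi: {count: 1, mode: min}
  Dicer_Alt:
    required:
      Ribonuclease_3: {count: 1, mode: min}
    alternatives:
      - [DEAD, PAZ]

rid:
  RID_candidate:
    required:
      DNA_methylase: {count: 2, mode: min}

light:
  Bac_rhodopsin:
    required:
      Bac_rhodopsin: {count: 1, mode: min}
  DNA_photolyase:
    required:
      DNA_photolyase: {count: 1, mode: min}
  FAD_binding_7:
    required:
      FAD_binding_7: {count: 1, mode: min}
  PHY:
    required:
      PHY: {count: 1, mode: min}
  GpcrRhopsn4:
    required:
      GpcrRhopsn4: {count: 1, mode: min}
  GAF:
    required:
      GAF: {count: 1, mode: min}
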