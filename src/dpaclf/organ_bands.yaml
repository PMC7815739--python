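# Organ-failure band tables for the CLIF family of scores.
#
# Each "breaks" list gives ascending lower-open band edges for the variable;
# a value v falls in band i where breaks[i-1] <= v < breaks[i] (v < breaks[0]
# is band 0), and "points" maps band index -> sub-score.  Overrides (renal
# replacement, vasopressors) are applied after the lookup.
#
# clif_sofa: six organs scored 0-4 (sum 0-24).  Also used as the HBV-SOFA
# grid inside the COSSH-ACLF score.
# clif_of:   six organs scored 1-3 (sum 6-18), the organ-function grid of
#            the CLIF-C ACLF score.
version: 1
clif_sofa:
  liver_tb_mg_dl:
    breaks: [1.2, 2.0, 6.0, 12.0]
    points: [0, 1, 2, 3, 4]
  kidney_cr_mg_dl:
    breaks: [1.2, 2.0, 3.5, 5.0]
    points: [0, 1, 2, 3, 4]
    renal_replacement_points: 4
  cerebral_he_stage:
    breaks: [1, 2, 3, 4]
    points: [0, 1, 2, 3, 4]
  coagulation_inr:
    breaks: [1.1, 1.25, 1.5, 2.5]
    points: [0, 1, 2, 3, 4]
  circulation_map_mmhg:
    # descending variable: MAP >= 70 scores 0, below scores 1
    breaks: [70.0]
    points: [1, 0]
    vasopressor_points: 3
  respiration_pao2_fio2:
    # descending variable: higher ratio is healthier
    breaks: [100.0, 200.0, 300.0, 400.0]
    points: [4, 3, 2, 1, 0]
clif_of:
  liver_tb_mg_dl:
    breaks: [6.0, 12.0]
    points: [1, 2, 3]
  kidney_cr_mg_dl:
    breaks: [2.0, 3.5]
    points: [1, 2, 3]
    renal_replacement_points: 3
  cerebral_he_stage:
    breaks: [1, 3]
    points: [1, 2, 3]
  coagulation_inr:
    breaks: [2.0, 2.5]
    points: [1, 2, 3]
  circulation_map_mmhg:
    breaks: [70.0]
    points: [2, 1]
    vasopressor_points: 3
  respiration_pao2_fio2:
    breaks: [200.0, 300.0]
    points: [3, 2, 1]
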