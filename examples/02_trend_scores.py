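"""Score one patient's lab trends and the cohort's SDTs distribution.

Each indicator (TB, Cr, PTA, HE stage) scores 1 (improving beyond the
band), 2 (within the band), or 3 (deteriorating beyond it); their sum SDTs
ranges 4-12 and is the dynamic component of DP-ACLF.
"""

from dpaclf import SimConfig, assess_trends, simulate_cohort, trend_table
from dpaclf.cohort import landmark_filter

cohort = simulate_cohort(SimConfig(n=300, seed=2))
patient = cohort.records[0]

a = assess_trends(patient, "week1")
print(f"{patient.patient_id} at week 1: TB={a.tb_score} Cr={a.cr_score} "
      f"PTA={a.pta_score} HE={a.he_score}  ->  SDTs={a.sdts}")
# A score of 3 on TB means bilirubin rose more than 30% from admission;
# 1 on PTA would mean prothrombin activity *improved* more than 30%.

alive = landmark_filter(cohort, "week1")
tt = trend_table(alive, "week1")
print(f"\nSDTs distribution at week 1 (n={len(tt)} patients alive and assessed):")
print(tt.sdts.value_counts().sort_index().to_string())
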