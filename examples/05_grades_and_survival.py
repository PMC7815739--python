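"""Grade patients by DP-ACLF and compare survival across grades.

Grades: I (score < 8), II (8-12), III (> 12).  Kaplan-Meier survival at
28 and 90 days should separate sharply by grade when the score carries
real prognostic signal.
"""

from dpaclf import DPACLFModel, SimConfig, km_logrank, simulate_cohort
from dpaclf.cohort import landmark_filter
from dpaclf.pipeline import score_table

cohort = simulate_cohort(SimConfig(n=1500, seed=4))
alive = landmark_filter(cohort, "week2")
st = score_table(alive, "week2", DPACLFModel.published())

rep = km_logrank(st.grade, st.survival_days, st.death90, horizons=(28, 90))
print("grade   n    events   S(28d)   S(90d)")
for g in sorted(rep.groups, key=lambda g: g.group):
    print(f"  {g.group:3s} {g.n:5d} {g.n_events:7d}   {g.survival_at[28.0]:.3f}    "
          f"{g.survival_at[90.0]:.3f}")
print(f"log-rank chi2 = {rep.logrank_statistic:.1f} "
      f"(df {rep.logrank_df}), p = {rep.logrank_p:.2e}")
# Survival falls steeply from grade I to III; the log-rank test quantifies
# how unlikely such separation would be if the grades were prognostically
# equivalent.
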