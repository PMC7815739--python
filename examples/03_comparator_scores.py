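"""Compute the six comparator severity scores for one lab panel.

CTP, MELD, MELD-Na, CLIF-SOFA, CLIF-C ACLF and COSSH-ACLF are the
established scores the dynamic model is benchmarked against.
"""

from dpaclf import LabPanel, ScoreName, compute_score

panel = LabPanel(
    timepoint="admission", tb=18.0, cr=1.4, pta=30.0, inr=2.1, na=131.0,
    albumin=2.6, he_stage=2, wbc=11.0, map=78.0, pao2_fio2=350.0,
    ascites="mild",
)

for name in ScoreName:
    sp = compute_score(name, panel, age=55.0)
    print(f"{name.value:12s} {sp.value:7.2f}   components: {sp.subscores or '-'}")
# Higher is worse on every scale; MELD ~25+ or CLIF-C ACLF ~50+ mark the
# range where 90-day mortality becomes likely in ACLF cohorts.
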