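"""Produce a baseline-characteristics (Table-1-style) report for a cohort.

Categorical covariates are summarized as count (%) per event group with a
Yates-corrected chi-square p-value; numeric covariates as mean (SD) with a
Kruskal-Wallis p-value; p <= 0.05 is starred.
"""

from daptsurv import describe_cohort, simulate_cohort, study_like_config

cohort = simulate_cohort(study_like_config(n=3000, seed=5))
table = describe_cohort(cohort)
text = table.render()
# print only the head of the table; the full frame is available via to_frame()
print("\n".join(text.splitlines()[:14]))
print("...")
frame = table.to_frame()
n_sig = int(frame["significant"].fillna(False).sum())
print(f"\n{n_sig}/{len(frame)} characteristics differ significantly between "
      "event and non-event groups (expected: the ones carrying true effects).")
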