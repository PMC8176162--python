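"""Generate a synthetic 40-patient cohort from the packaged group distributions.

The packaged defaults reproduce the published group summaries (18 fluid
responders, 22 non-responders; per-variable normal parameters at the four
protocol time points), so the cohort statistically resembles the study
population the analysis was designed for.
"""

from fluidresp import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=2024))

print(f"Patients: {len(cohort)}  "
      f"(responders {int(cohort['responder'].sum())}, "
      f"non-responders {int((~cohort['responder']).sum())})")
print()
for group in ("responder", "nonresponder"):
    sub = cohort[cohort.group == group]
    print(f"{group:>13}:  dPPV = {sub.delta_ppv.mean():+.1f} ± {sub.delta_ppv.std():.1f}   "
          f"dSVV = {sub.delta_svv.mean():+.1f} ± {sub.delta_svv.std():.1f}   "
          f"SV T3->T4 = {(sub.SV_T4 - sub.SV_T3).mean():+.1f} mL")
print()
print("Responders show a positive PEEP-challenge delta and a large stroke-volume")
print("rise after fluid loading; non-responders are flat on both, mirroring the")
print("published group means within sampling noise at n = 18/22.")
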