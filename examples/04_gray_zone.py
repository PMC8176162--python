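"""Gray-zone analysis: where is a single dSVV measurement inconclusive?

Computes both inconclusive-range constructions for the PEEP-challenge
dSVV on a synthetic cohort: the 95% bootstrap CI of the Youden-optimal
cutoff (1,000 stratified resamples) and the split-curve zone where
neither sensitivity nor specificity reaches 90%.
"""

from fluidresp import (
    CohortSpec,
    bootstrap_thresholds,
    count_inside,
    empirical_roc,
    generate_cohort,
    gray_zone_from_bootstrap,
    split_curve_zone,
    youden_cutoff,
)

cohort = generate_cohort(CohortSpec(seed=42))
scores = cohort["delta_svv"].to_numpy()
labels = cohort["responder"].to_numpy()

curve = empirical_roc(scores, labels, predictor_name="delta_svv")
cutoff = youden_cutoff(curve).cutoff
thresholds = bootstrap_thresholds(scores, labels, B=1000, seed=7)
zone_boot = gray_zone_from_bootstrap(thresholds)
zone_split = split_curve_zone(curve, se_floor=0.90, sp_floor=0.90)

print(f"Youden-optimal dSVV cutoff: > {cutoff:.2f} points")
print(f"Bootstrap 95% CI of the cutoff: {zone_boot.low:.2f} to {zone_boot.high:.2f} "
      f"({count_inside(scores, zone_boot)} of {len(scores)} patients inside)")
if zone_split.is_empty:
    print("Split-curve zone (Se/Sp >= 90%): empty - every value is conclusive")
else:
    print(f"Split-curve zone (Se or Sp < 90%): {zone_split.low:.2f} to {zone_split.high:.2f} "
          f"({count_inside(scores, zone_split)} patients inside)")
print()
print("Patients whose delta falls inside a zone cannot be confidently called")
print("responder or non-responder from this index alone; a narrow zone with few")
print("patients inside is what makes the PEEP-challenge delta clinically usable.")
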