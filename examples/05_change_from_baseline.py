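"""Change-from-baseline summary on the calibrated cohort.

Draws n=101 patients from the preset calibrated to the published cohort
summary and prints mean ± SD change from baseline per OABSS item and
total at each follow-up; negative values are improvements.
"""

from oabnet import change_summary, generate_cohort, severity_band, table1_calibrated_preset
from oabnet.simulate import TABLE1_TOTAL_MEAN_CHANGE

cohort = generate_cohort(table1_calibrated_preset(seed=42))
cs = change_summary(cohort)

print(f"n = {cs.n} patients; change from baseline (mean ± SD):\n")
print(cs.to_table().to_string())

print("\ncalibration targets for the mean total change:")
for t in ("T6", "T12", "T18", "T24"):
    print(f"  {t}: computed {cs.mean('total', t):+.4f}, "
          f"target {TABLE1_TOTAL_MEAN_CHANGE[t]:+.4f}")

t0 = int(cohort.totals()[0, 0])
print(f"\nseverity bands: patient {cohort.patient_ids[0]} baseline total "
      f"{t0} -> {severity_band(t0)!r}")
print("Improvement peaks at 6-12 months (about -1.6 points) and partially "
      "regresses by 24 months (about -0.8), matching the published pattern.")
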