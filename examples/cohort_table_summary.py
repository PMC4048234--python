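"""Summarise the packaged clinical cohort table.

Loads the packaged transcription of the study cohort (60 patients,
three staining markers) and prints per-group clinical summaries and
per-marker islet totals.
"""
import isletquant as iq

records = iq.load_reference_cohort()
summary = iq.summarize_cohort(records)

for grp in ("ND", "T2D"):
    print(f"{grp}: {summary.n_patients[grp]} patients, "
          f"age {summary.mean_age[grp]:.1f} ± {summary.sd_age[grp]:.1f} y, "
          f"BMI {summary.mean_bmi[grp]:.1f} ± {summary.sd_bmi[grp]:.1f} kg/m^2, "
          f"sources {summary.source_counts[grp]}")
print(f"islets pictured: {summary.islet_totals['overall']} total "
      f"(TMEM27 {summary.islet_totals['tmem27']}, "
      f"BACE2 {summary.islet_totals['bace2']}, "
      f"insulin {summary.islet_totals['insulin']})")
print("mean islets per patient: "
      + ", ".join(f"{m} {v:.1f}" for m, v in summary.mean_islets_per_patient.items()))
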