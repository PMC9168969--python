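"""Generate a 30-patient virtual screening cohort.

Each patient gets an age (fixing the 18- or 24-month screening interval),
a TVDT sampled from the clinical fit, a first-round diameter uniform on
3.5-13 mm, and breast metadata; the second-round diameter follows from
the exponential growth law.
"""

import numpy as np

import tvdtsim as tv

cohort = tv.generate_cohort(tv.CohortConfig(n=30, seed=1))

tvdts = np.array([p.tvdt for p in cohort])
d2 = np.array([p.d_round2 for p in cohort])
print(f"cohort mean TVDT: {tvdts.mean():.0f} d (SD {tvdts.std(ddof=1):.0f} d)")
print(f"second-round sizes: {d2.min():.1f}-{d2.max():.1f} mm")
print(f"tumors beyond palpable size (>20 mm) at round 2: "
      f"{sum(p.palpable for p in cohort)} (flagged, not removed)")

tv.write_cohort(cohort, "cohort.csv")
print("wrote cohort.csv; the cohort mean varies around 297 d with "
      "SE ~ 169/sqrt(30) ~ 31 d between replicate cohorts")
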