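"""Longitudinal arteriole-venule analysis on a conserved synthetic cohort.

Simulates six replicates measured at five timepoints where the paired
arteriole and venule share the same true flow change (conservation through
the vascular bed), then fits venule flow change against arteriole flow
change and decomposes the changes with the V/D² ratio.
"""

from oculoflow import (conservation_analysis, simulate_conserved_cohort,
                       summarize_cohort, v_over_d2_ratio)
from oculoflow.core import LongitudinalSeries, VesselMeasurement

cohort = simulate_conserved_cohort(rng_seed=3)
print(f"cohort: {cohort.replicate.nunique()} replicates x "
      f"{cohort.timepoint.nunique()} timepoints x 2 vessels")

for pool in ("replicates", "means"):
    res = conservation_analysis(cohort, pool=pool)
    print(f"conservation fit ({pool}): slope {res['slope']:.2f}, "
          f"R^2 {res['r_squared']:.3f} over {res['n_points']} points")
print("R^2 near 1 = flow entering arterioles leaves through venules")

summary = summarize_cohort(
    cohort[cohort.vessel_type == "venule"], "diameter_um",
    timepoint_order=["baseline", "6h", "24h", "72h", "10d"])
print("\nvenule diameter (um), mean +/- SD per timepoint:")
print(summary.round(2).to_string(index=False))

# V/D² decomposition for one replicate: positive = velocity-dominated
# (arteriole-like), negative = dilation-dominated (venule-like)
rep = cohort[cohort.replicate == 0]
for vtype in ("arteriole", "venule"):
    rows = rep[rep.vessel_type == vtype]
    ms = [VesselMeasurement(f"{vtype}-0", vtype, r.timepoint,
                            r.velocity_mm_s, r.diameter_um, r.flow_nl_s)
          for r in rows.itertuples()]
    series = LongitudinalSeries(f"{vtype}-0", vtype, ms)
    ratio = v_over_d2_ratio(series)
    peak = ratio.v_over_d2_change_pct.iloc[2]
    print(f"{vtype}: V/D^2 change at peak timepoint {peak:+.1f}%")
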