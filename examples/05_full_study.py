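"""The full seven-subject SINGLE vs MULTI comparison on synthetic data.

Generates a cohort of seven synthetic runners, processes every trial with
both foot models, and runs the complete statistical battery: Hotelling
T^2 fields on ankle angles / angular velocities / moments with
Sidak-gated post-hoc t fields, paired t fields on joint power, and
Bonferroni-corrected scalar tests on joint work.
"""

import numpy as np

import footmech as fm

bundles = [fm.generate_running_trial(s)[0] for s in fm.study_specs(7, seed=0)]
res = fm.run_study(bundles, seed=0)

print(f"subjects: {res.n_subjects}")
for name, spm in res.spm.items():
    state = f"{len(spm.clusters)} significant cluster(s)" if spm.clusters else "n.s."
    print(f"  {name:28s} threshold {spm.threshold:7.2f} -> {state}")

for name, t in res.work_tests.items():
    mark = "*" if t["significant"] else " "
    print(f"  {name:34s}{mark} diff {t['mean_difference']:+.3f} J/kg "
          f"(p = {t['p']:.2e})")

excS = np.mean([fm.excursion(a[:, 0]) for a in res.fields["ankle_angle_SINGLE"]])
excM = np.mean([fm.excursion(a[:, 0]) for a in res.fields["ankle_angle_MULTI"]])
wp = res.work_partition
print(f"\nsagittal ankle excursion: SINGLE {excS:.1f} deg vs MULTI {excM:.1f} deg")
print(f"positive work: SINGLE ankle {wp['single_ankle_positive']:.3f} J/kg; "
      f"MULTI ankle {wp['multi_ankle_positive']:.3f} + "
      f"midfoot {wp['multi_midfoot_positive']:.3f} J/kg "
      f"({100 * wp['relative_discrepancy']:.1f}% partition discrepancy)")
# A single-segment foot model inflates ankle excursion and push-off work;
# the inflation is accounted for by the midfoot joint it omits.
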