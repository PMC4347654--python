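"""Full method-comparison study on a synthetic cohort.

Eight phantoms with varying infarct extent are analysed by two simulated
observers (seeded contour and ROI jitter), twice each; three observers
contribute manual analyses whose mean per subject is the reference standard
(six analyses). The report mirrors a method-comparison table: per-method
mean +/- SD, ICC and Bland-Altman bias against the manual reference, and
interobserver / intraobserver agreement.
"""

import numpy as np

from cmrquant import CohortConfig, PhantomSpec, SubjectEntry, run_cohort

subjects = [
    SubjectEntry(
        subject_id=f"P{i:02d}",
        spec=PhantomSpec(
            matrix_size=96, endo_radius=15.0, epi_radius=25.0, n_slices=6,
            infarct_slice_span=(1, 5),
            infarct_angular_extent=50.0 + 12.0 * i,
            infarct_transmurality=0.5 + 0.05 * i,
            si_lge_border=170.0, blur_sigma_mm=0.8, speckle_count=2,
        ),
    )
    for i in range(8)
]
config = CohortConfig(subjects=subjects, measures=("IS", "AAR"), seed=11)
ratings, reports, provenance = run_cohort(config)

true_is = np.mean([s["true_is"] for s in provenance["subjects"].values()])
print(f"{len(ratings)} measurements; mean true IS = {true_is:.2f} %LVM\n")
cols = ["method", "mean", "sd", "icc_v_ref", "bias", "interobs_icc", "intraobs_icc"]
for key in (("1.5T", "IS"), ("1.5T", "AAR")):
    print(f"--- {key[1]} ---")
    print(reports[key][cols].round(3).to_string(index=False))
    print()
# Low-k SD thresholds and per-slice Otsu run above the manual reference
# (positive bias); FWHM tracks it closely with the tightest interobserver
# agreement -- the qualitative pattern seen in clinical method comparisons.
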