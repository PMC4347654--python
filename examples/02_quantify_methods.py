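"""Quantify infarct size on one phantom with every thresholding method.

A remote 2 cm^2 ROI (placed opposite the infarct, off the partial-volume
rim) drives the kSD thresholds; FWHM takes half the brightest myocardial
voxel; per-slice Otsu needs no ROI at all. Corrections [a] (fill enclosed
hypointense cores) and [b] (drop enhancement without interslice continuity)
are applied to every method before the %LVM is computed.
"""

from cmrquant import PhantomSpec, build_roi, generate_phantom, quantify_stack
from cmrquant.phantom import remote_seed

spec = PhantomSpec(
    si_lge_border=170.0,  # peri-infarct border zone of intermediate signal
    blur_sigma_mm=0.8,
    mvo_fraction=0.15,
    speckle_count=3,
    infarct_slice_span=(2, 6),
    seed=7,
)
lge, _, _, truth = generate_phantom(spec)
myo = truth.to_myo_mask()  # most apical slice excluded by default

sl, r, c = remote_seed(spec)
remote = build_roi(myo, lge, sl, (r, c), target_area_cm2=2.0, avoid_rim_px=1)
print(f"remote ROI: {remote.n_voxels} voxels on slice {sl}")
print(f"true IS = {truth.true_is_percent_lvm:.2f} %LVM\n")

print(f"{'method':>8} {'threshold':>10} {'IS %LVM':>9} {'error':>7}")
for k in (5, 6, 7, 8):
    res = quantify_stack(lge, myo, "ksd", remote_roi=remote, k=k)
    print(f"{res.method:>8} {res.thresholds[2]:>10.1f} {res.percent_lvm:>9.2f} "
          f"{res.percent_lvm - truth.true_is_percent_lvm:>+7.2f}")
for method in ("fwhm", "otsu"):
    res = quantify_stack(lge, myo, method)
    t = res.thresholds[2]
    print(f"{res.method:>8} {t:>10.1f} {res.percent_lvm:>9.2f} "
          f"{res.percent_lvm - truth.true_is_percent_lvm:>+7.2f}")
# Expected pattern: the 5SD threshold sits below the border-zone signal and
# overestimates; 8SD and especially FWHM stay close to the truth; per-slice
# Otsu overestimates because it assigns enhancement on every slice.
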