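"""Agatston coronary calcium score on the noncontrast phantom.

Lesions are 8-connected in-plane groups of voxels at or above 130 HU with
area >= 1 mm^2; each contributes area times a peak-HU weight, normalized to
the classic 3 mm slice protocol.
"""

from eatkit import PhantomSpec, agatston_score, generate_phantom_pair

spec = PhantomSpec(seed=47)
noncontrast, _, _, _ = generate_phantom_pair(spec)

score = agatston_score(noncontrast)
print(f"plaque peak HU       : {spec.plaque_peak_hu:.0f}")
print(f"Agatston score       : {score:.2f}")
# The phantom contains one small plaque (peak 300 HU -> weight 3); scores on
# real scans sum over every lesion on every slice. Contrast-enhanced input is
# refused because iodinated blood crosses the 130 HU threshold.
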