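"""Sample perivascular fat in cylinders around coronary centerlines.

A 4 mm-radius tube follows each vessel over a 40 mm arc-length window
(starting 10 mm from the ostium for the right coronary artery); HU-band
thresholds then select the fat voxels inside the tube.
"""

from eatkit import PhantomSpec, compute_eat_stats, generate_phantom_pair
from eatkit.segmentation import VESSEL_WINDOWS, pericoronary_cylinder_mask

_, contrast, _, centerlines = generate_phantom_pair(PhantomSpec(seed=31))

for vessel, centerline in centerlines.items():
    start, length = VESSEL_WINDOWS[vessel]
    cylinder = pericoronary_cylinder_mask(
        contrast, centerline, radius=4.0, start_offset=start, length=length
    )
    stats = compute_eat_stats(contrast, cylinder)
    print(f"{vessel.upper():4s} window [{start:4.0f}, {start + length:4.0f}] mm: "
          f"{int(cylinder.voxels.sum()):6d} voxels in cylinder, "
          f"dispersion {stats.dispersion:6.2f} HU")
# All three vessels share the phantom's mixture parameters, so the three
# dispersions agree up to sampling noise.
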