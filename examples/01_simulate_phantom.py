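"""Simulate a two-time-point synthetic bone-SPECT/CT subject.

Builds the default subject (three spherical metastases with true fractional
uptake changes +50 %, 0 %, -50 %; one vertebral reference region), draws
Poisson count volumes for both time points, and prints the ground truth.
"""

from bonetrack import default_phantom, ground_truth_table, make_longitudinal_pair

spec = default_phantom(3, (0.5, 0.0, -0.5))
tp1, tp2 = make_longitudinal_pair(spec, seeds=(1, 2))

print("grid:", spec.grid.shape, "voxels at", spec.grid.spacing, "mm")
print(f"TP1 counts: total {tp1.counts.data.sum():.0f}, max/voxel {tp1.counts.data.max():.0f}")
print(f"TP2 counts: total {tp2.counts.data.sum():.0f}, max/voxel {tp2.counts.data.max():.0f}")
print()
print(ground_truth_table(spec).to_string(index=False))
# true_change is the fractional SUV change painted into the phantom; the
# true_category column is what a perfect classifier should recover.
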