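"""Build the default digital phantom and inspect its anatomy.

The phantom hosts mirror-symmetric striatum and midbrain (SNc/VTA-like)
seed ROIs.  Each striatal territory (limbic, prefrontal, sensorimotor) is
wired to its own cortical target group by a straight fiber bundle; each
midbrain territory is wired to the matching striatal territory by a curved
bundle.  The orientation field stores a small direction/weight mixture per
voxel, standing in for a fiber orientation distribution.
"""

import midparc as mp

spec = mp.default_phantom_spec(grid_shape=(64, 64, 64), rng_seed=0)
phantom = mp.build_phantom(spec)

print("Seed ROIs (voxels):")
for name, mask in phantom.seed_masks.items():
    print(f"  {name:12s} {int(mask.sum()):5d}")

print("\nGround-truth territories of striatum_R (voxels):")
truth = phantom.ground_truth.territories["striatum_R"]
for k, lab in enumerate(mp.TERRITORY_LABELS, start=1):
    print(f"  {lab:13s} {int((truth == k).sum()):5d}")

covered = phantom.field.total_weight() > 0
print(f"\nOrientation field covers {int(covered.sum())} voxels; "
      "every seed voxel lies inside a bundle, so streamlines can be "
      "launched anywhere in a seed ROI.")
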