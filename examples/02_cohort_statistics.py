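"""Draw a phantom cohort and check its angle distributions.

The cohort generator draws per-bone pose angles from normal distributions
whose defaults are the study population's software-measured means and SDs.
Ground-truth angles are analytic, so a large cohort can be summarized
without voxelizing a single volume.  The printed sample moments should sit
within Monte-Carlo error of the configured ones.
"""
import numpy as np

from carpalign import sample_cohort
from carpalign.phantom import DEFAULT_ANGLE_MEANS, DEFAULT_ANGLE_SDS
from carpalign.volume import MEASURED_BONES

cohort = sample_cohort(2000, seed=1)

print(f"{'bone':<18} {'target':>14} {'sample':>15}")
for bone in MEASURED_BONES:
    draws = np.array([ph.pose.angle(bone) for ph in cohort])
    print(
        f"{bone.short:<18} {DEFAULT_ANGLE_MEANS[bone]:6.0f} ({DEFAULT_ANGLE_SDS[bone]:.0f})"
        f"   {draws.mean():8.2f} ({draws.std(ddof=1):.2f})"
    )
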