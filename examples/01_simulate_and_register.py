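"""Generate a synthetic wing skeleton and recover its poses by registration.

Builds tenth-size bone clouds in three postures (known ground truth from the
measured falcon kinematics), registers each folded cloud to its extension
reference, and compares recovered rotation angles to the truth.
"""

import numpy as np

from wingkin import FitOptions, fit_all
from wingkin.geometry import rotation_to_axis_angle
from wingkin.synthetic import (
    compose_chain,
    default_specs,
    generate_bone_cloud,
    make_table1_poses,
    pose_clouds,
)

seed = 1
specs = default_specs(seed=seed, subsample=10)  # ~180-980 points per bone
base = {bone: generate_bone_cloud(s) for bone, s in specs.items()}
truth = compose_chain(make_table1_poses())
clouds = pose_clouds(base, truth, overlap_fraction=0.8, seed=seed)

fits = fit_all(clouds, FitOptions(n_starts=12, seed=seed))

print(f"{'bone':<12} {'posture':<15} {'true':>7} {'recovered':>9} {'resid mm':>9}")
for bone, per_bone in fits.items():
    for posture in ("half_extension", "flexion"):
        true_angle = truth[bone][posture].transform.rotation_angle_deg()
        rec = per_bone[posture]
        print(f"{bone:<12} {posture:<15} {true_angle:7.2f} "
              f"{rec.rotation_angle_deg():9.2f} {rec.residual_mm:9.3f}")

# The recovered column should match the true column to a few tenths of a
# degree; the residual column sits near the 0.2 mm noise floor.
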