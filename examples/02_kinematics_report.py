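"""Axis-angle kinematics table of the folding wing from known poses.

Feeds the measured ground-truth transforms straight into the reporting
stage: the table reproduces the measured per-bone axes and angles, the axis
deviation between the two folded postures, and the flexion/half-extension
angle ratio (folding roughly doubles each rotation).
"""

from wingkin import make_report
from wingkin.synthetic import compose_chain, make_table1_poses

absolute = compose_chain(make_table1_poses())
fits = {bone: {p: gt.transform for p, gt in per.items()}
        for bone, per in absolute.items()}

report = make_report(fits)
print(report.round(2).to_string(index=False))

# theta_half_deg / theta_flex_deg are each bone's rotation relative to its
# chain parent (ulna & radius on the humerus, metacarpal on the ulna, digit
# II on the metacarpal); axis_deviation_pct = 100*sin of the angle between
# the two posture axes; flexion_half_ratio near 2 means folding doubles
# every joint rotation.
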