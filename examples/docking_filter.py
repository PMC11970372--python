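"""Geometric filtering of docked enzyme-substrate conformations.

Filters a handful of hand-built poses by the catalytic criterion: the
substrate's reactive atom must sit within 5 Å of the iron-oxo (FeO) centre
and the docking score must be negative.
"""

from haplotax import dock_filter as dk

poses = [
    dk.DockPose("pose1", -7.2, (1.0, 2.0, 3.0), (1.0, 2.0, 6.5)),  # 3.5 A
    dk.DockPose("pose2", -6.8, (0.0, 0.0, 0.0), (3.0, 4.0, 0.0)),  # 5.0 A
    dk.DockPose("pose3", -9.1, (0.0, 0.0, 0.0), (6.0, 0.0, 0.0)),  # 6.0 A
    dk.DockPose("pose4", +0.4, (0.5, 0.0, 0.0), (2.5, 0.0, 0.0)),  # unfavourable
]
for p in poses:
    print(f"{p.pose_id}: distance {dk.pose_distance(p):.1f} A, "
          f"score {p.score:+.1f} kcal/mol")

kept = dk.filter_poses(poses, max_dist=5.0)
print("\nretained (catalytically reasonable) poses:",
      [p.pose_id for p in kept])
# pose3 fails the 5 A distance bound; pose4 has a positive (unfavourable)
# score; the survivors are ordered by distance, then score
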