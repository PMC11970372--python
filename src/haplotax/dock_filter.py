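"""Geometric filtering of docked conformations.

A docked pose is kept when the distance from the substrate's reactive atom
to the iron-oxo (FeO) centre of the enzyme is within a catalytic cutoff
(default 5 Å, inclusive) and the docking score is negative (favourable).
Poses arrive as a pre-extracted table of score plus two coordinate triples;
which substrate atom counts as the reactive site is the caller's choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class DockPose:
    pose_id: str
    score: float  # kcal/mol
    reactive_atom_xyz: tuple[float, float, float]
    fe_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        coords = (*self.reactive_atom_xyz, *self.fe_xyz, self.score)
        if not all(math.isfinite(v) for v in coords):
            raise ValueError(f"pose {self.pose_id}: non-finite value")


def pose_distance(pose: DockPose) -> float:
    """Euclidean reactive-atom-to-Fe distance in Å."""
    return math.dist(pose.reactive_atom_xyz, pose.fe_xyz)


def filter_poses(
    poses: Sequence[DockPose],
    max_dist: float = 5.0,
    require_negative_score: bool = True,
) -> list[DockPose]:
    """Keep catalytically reasonable poses; sort by distance, then score.

    distance <= max_dist is inclusive ("within 5 Å"); score must be
    strictly negative when required.  The empty result is allowed.
    """
    kept = [
        p
        for p in poses
        if pose_distance(p) <= max_dist
        and (p.score < 0 or not require_negative_score)
    ]
    kept.sort(key=lambda p: (pose_distance(p), p.score, p.pose_id))
    return kept


def read_poses_tsv(path: str | Path) -> list[DockPose]:
    """Read poses from a TSV: id, score, x1, y1, z1, x2, y2, z2 (header row)."""
    poses: list[DockPose] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty pose table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise ValueError(
                    f"{path}: line {lineno}: expected 8 columns"
                )
            vals = [float(v) for v in fields[1:]]
            poses.append(
                DockPose(
                    fields[0],
                    vals[0],
                    (vals[1], vals[2], vals[3]),
                    (vals[4], vals[5], vals[6]),
                )
            )
    return poses


__all__ = ["DockPose", "pose_distance", "filter_poses", "read_poses_tsv"]
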