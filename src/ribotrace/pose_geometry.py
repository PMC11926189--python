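"""Rigid-body pose geometry for subtomogram particles.

Each particle stores ZYZ Euler angles (rot, tilt, psi) describing its
orientation relative to the subtomogram average (the reference frame).
Marker points -- here the ribosomal mRNA entry and exit sites -- are
defined once as offsets from the particle centre in the reference frame
and mapped into tomogram coordinates through the particle pose.

Rotation convention
-------------------
``euler_to_rotation`` returns ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``
(intrinsic ZYZ).  Whether a reference-frame offset ``v`` maps into the
tomogram as ``R @ v`` or ``R.T @ v`` depends on which direction the
alignment software stored; this is the classic silent-error trap in
subtomogram tooling, so the direction is an explicit switch
(``map_direction`` in :class:`MarkerConfig`) and
:func:`export_marker_clouds` renders both candidate clouds for visual
validation against a map.  The default ``"inverse"`` (``R.T @ v``) treats
the stored angles as the rotation that aligns the particle onto the
reference, the convention the synthetic generator also emits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from ribotrace.star_io import ParticleSet

__all__ = [
    "MarkerConfig",
    "euler_to_rotation",
    "rotation_matrices",
    "map_marker",
    "map_markers",
    "export_marker_clouds",
]

MapDirection = Literal["forward", "inverse"]


@dataclass
class MarkerConfig:
    """mRNA entry/exit marker offsets and tracing cut-offs.

    Offsets are in Å in the subtomogram-average frame, relative to the
    particle centre.  ``trace_cutoff`` (default 250 Å = 25 nm) bounds
    exit-to-entry links during polysome tracing; ``distance_cutoff``
    (default 500 Å = 50 nm) is the looser bound used for neighbour
    distance distributions.
    """

    entry_offset: np.ndarray = field(default_factory=lambda: np.array([55.0, 0.0, 0.0]))
    exit_offset: np.ndarray = field(default_factory=lambda: np.array([-55.0, 0.0, 20.0]))
    trace_cutoff: float = 250.0
    distance_cutoff: float = 500.0
    map_direction: MapDirection = "inverse"

    def __post_init__(self) -> None:
        self.entry_offset = np.asarray(self.entry_offset, float)
        self.exit_offset = np.asarray(self.exit_offset, float)
        if self.entry_offset.shape != (3,) or self.exit_offset.shape != (3,):
            raise ValueError("marker offsets must be 3-vectors")
        if not (np.isfinite(self.entry_offset).all() and np.isfinite(self.exit_offset).all()):
            raise ValueError("marker offsets must be finite")
        if self.trace_cutoff <= 0 or self.distance_cutoff <= 0:
            raise ValueError("cut-offs must be positive")
        if self.trace_cutoff > self.distance_cutoff:
            raise ValueError("trace_cutoff must not exceed distance_cutoff")
        if self.map_direction not in ("forward", "inverse"):
            raise ValueError("map_direction must be 'forward' or 'inverse'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "MarkerConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            entry_offset=np.asarray(raw["entry_offset"], float),
            exit_offset=np.asarray(raw["exit_offset"], float),
            trace_cutoff=float(raw.get("trace_cutoff", 250.0)),
            distance_cutoff=float(raw.get("distance_cutoff", 500.0)),
            map_direction=raw.get("map_direction", "inverse"),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "entry_offset": self.entry_offset.tolist(),
                    "exit_offset": self.exit_offset.tolist(),
                    "trace_cutoff": float(self.trace_cutoff),
                    "distance_cutoff": float(self.distance_cutoff),
                    "map_direction": self.map_direction,
                },
                fh,
                sort_keys=False,
            )


def euler_to_rotation(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ Euler angles (degrees) to a 3x3 rotation matrix.

    ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` (intrinsic composition).
    """
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def rotation_matrices(eulers: np.ndarray) -> np.ndarray:
    """Vectorised :func:`euler_to_rotation` for an (n, 3) angle array."""
    eulers = np.atleast_2d(np.asarray(eulers, float))
    return Rotation.from_euler("ZYZ", eulers, degrees=True).as_matrix()


def _pose_matrices(eulers: np.ndarray, direction: MapDirection) -> np.ndarray:
    R = rotation_matrices(eulers)
    if direction == "inverse":
        R = np.swapaxes(R, -1, -2)
    return R


def map_marker(
    position: np.ndarray,
    euler: tuple[float, float, float],
    offset: np.ndarray,
    direction: MapDirection = "inverse",
) -> np.ndarray:
    """Map one reference-frame offset into tomogram coordinates."""
    A = _pose_matrices(np.asarray(euler, float)[None, :], direction)[0]
    return np.asarray(position, float) + A @ np.asarray(offset, float)


def map_markers(
    particles: ParticleSet,
    offset: np.ndarray,
    direction: MapDirection | None = None,
) -> np.ndarray:
    """Map one marker offset for every particle; returns (n, 3) Å.

    ``direction`` defaults to ``"inverse"`` (see module docstring).
    """
    if direction is None:
        direction = "inverse"
    A = _pose_matrices(particles.eulers(), direction)
    return particles.positions() + np.einsum("nij,j->ni", A, np.asarray(offset, float))


def export_marker_clouds(
    particles: ParticleSet,
    markers: MarkerConfig,
    out_csv: str | os.PathLike,
) -> None:
    """Write entry/exit marker clouds under BOTH direction conventions.

    The CSV (particle_id, marker, direction, x, y, z) can be overlaid on a
    tomogram to decide which convention matches the data; load the winner
    into ``MarkerConfig.map_direction``.
    """
    import pandas as pd

    rows = []
    for direction in ("forward", "inverse"):
        for name, off in (("entry", markers.entry_offset), ("exit", markers.exit_offset)):
            pts = map_markers(particles, off, direction)
            rows.append(
                pd.DataFrame(
                    {
                        "particle_id": particles.df["particle_id"],
                        "marker": name,
                        "direction": direction,
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                        "z": pts[:, 2],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(out_csv, index=False)
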