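"""Reading and writing RELION-dialect particle STAR files.

A particle table carries, per subtomogram, the tomogram (= cell) it came
from, refined 3-D coordinates, ZYZ Euler angles and any number of
categorical label columns (e.g. a bS20 occupancy class).  On load,
coordinates are converted to ångströms, refined origin offsets are
subtracted, angles are normalised to canonical ranges and every particle
receives a sequential unique identifier in file order.

Both origin conventions in circulation are accepted:

* RELION 3.1: ``_rlnOriginX/Y/Z`` in pixels,
* RELION >= 4: ``_rlnOriginXAngst/...`` in ångströms.

The refined position is ``coordinate * pixel_size - origin_in_angstrom``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ParticleRecord",
    "ParticleSet",
    "StarFormatError",
    "read_particles",
    "write_particles",
    "normalize_euler",
]

COORD_COLS = ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ")
ANGLE_COLS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
ORIGIN_PX_COLS = ("_rlnOriginX", "_rlnOriginY", "_rlnOriginZ")
ORIGIN_ANGST_COLS = ("_rlnOriginXAngst", "_rlnOriginYAngst", "_rlnOriginZAngst")
TOMO_COLS = ("_rlnTomoName", "_rlnMicrographName", "_rlnImageName")

POLYSOME_COLS = ("_polysomeID", "_polysomeChainPosition", "_polysomeChainLength")
#: sentinel for particles outside any traced polysome
UNASSIGNED = -1


class StarFormatError(ValueError):
    """Raised when a STAR file lacks required columns or has bad values."""


@dataclass(frozen=True)
class ParticleRecord:
    """One subtomogram particle with pose and labels (positions in Å)."""

    particle_id: int
    tomo_id: str
    position: np.ndarray  # (3,) Å
    euler: tuple[float, float, float]  # (rot, tilt, psi) degrees, ZYZ
    labels: Mapping[str, str] = field(default_factory=dict)


@dataclass
class ParticleSet:
    """An ordered particle table plus load provenance.

    ``df`` columns: ``particle_id, tomo_id, x, y, z, rot, tilt, psi`` and
    one column per attached label.  Positions are in Å, angles in degrees
    (ZYZ, tilt in [0, 180], rot/psi in [-180, 180]).
    """

    df: pd.DataFrame
    pixel_size: float
    provenance: str = ""
    label_columns: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(float)

    def eulers(self) -> np.ndarray:
        return self.df[["rot", "tilt", "psi"]].to_numpy(float)

    def tomo_ids(self) -> np.ndarray:
        return self.df["tomo_id"].to_numpy()

    def labels_for(self, label: str) -> pd.Series:
        if label not in self.df.columns:
            raise KeyError(f"label column {label!r} not attached to this set")
        return self.df[label]

    def records(self) -> Iterable[ParticleRecord]:
        for row in self.df.itertuples(index=False):
            yield ParticleRecord(
                particle_id=int(row.particle_id),
                tomo_id=str(row.tomo_id),
                position=np.array([row.x, row.y, row.z], float),
                euler=(float(row.rot), float(row.tilt), float(row.psi)),
                labels={c: getattr(row, c) for c in self.label_columns},
            )

    def validate(self) -> None:
        pid = self.df["particle_id"].to_numpy()
        if not np.array_equal(pid, np.arange(len(pid))):
            raise ValueError("particle_id values must be contiguous from 0")
        if not np.isfinite(self.positions()).all():
            raise ValueError("non-finite particle position")


def normalize_euler(rot: np.ndarray, tilt: np.ndarray, psi: np.ndarray):
    """Map ZYZ angles to tilt in [0, 180], rot/psi in [-180, 180].

    Uses Rz(a)Ry(b)Rz(c) == Rz(a+180)Ry(-b)Rz(c+180) to flip negative
    tilts, then wraps rot/psi.  tilt values outside [-180, 180] are wrapped
    first so the flip identity applies.
    """
    rot = np.asarray(rot, float).copy()
    tilt = np.asarray(tilt, float).copy()
    psi = np.asarray(psi, float).copy()

    def wrap(a):
        return (a + 180.0) % 360.0 - 180.0

    tilt = wrap(tilt)
    neg = tilt < 0
    tilt[neg] = -tilt[neg]
    rot[neg] += 180.0
    psi[neg] += 180.0
    return wrap(rot), tilt, wrap(psi)


def _find_particle_block(doc: "gemmi.cif.Document") -> "gemmi.cif.Block":
    for block in doc:
        if block.find_values(COORD_COLS[0]):
            return block
    raise StarFormatError(
        f"no data block with column {COORD_COLS[0]} found"
    )


def _numeric(block, col: str, n: int, *, required: bool, path: str) -> np.ndarray | None:
    vals = block.find_values(col)
    if not vals:
        if required:
            raise StarFormatError(f"{path}: missing required column {col}")
        return None
    out = np.empty(len(vals), float)
    for i, v in enumerate(vals):
        try:
            out[i] = float(v)
        except ValueError as exc:
            raise StarFormatError(
                f"{path}: non-numeric value {v!r} in column {col}, row {i}"
            ) from exc
    if len(out) != n:
        raise StarFormatError(f"{path}: column {col} has {len(out)} rows, expected {n}")
    return out


def read_particles(
    path: str | os.PathLike,
    pixel_size: float,
    label_columns: Sequence[str] = (),
    tomo_column: str | None = None,
) -> ParticleSet:
    """Load a particle STAR file into a :class:`ParticleSet`.

    Parameters
    ----------
    path:
        STAR file with a data block containing ``_rlnCoordinateX/Y/Z`` and
        ``_rlnAngleRot/Tilt/Psi`` columns.
    pixel_size:
        Å per pixel of the coordinate columns.
    label_columns:
        Extra categorical columns to attach (named with or without the
        leading underscore; stored without it).
    tomo_column:
        Column holding the tomogram/cell identifier.  Defaults to the first
        of ``_rlnTomoName``, ``_rlnMicrographName``, ``_rlnImageName``
        present; a single-tomogram table without any of these gets the id
        ``"tomo_0"``.
    """
    path = os.fspath(path)
    doc = gemmi.cif.read_file(path)
    block = _find_particle_block(doc)

    n = len(block.find_values(COORD_COLS[0]))
    coords = np.column_stack(
        [_numeric(block, c, n, required=True, path=path) for c in COORD_COLS]
    )
    angles = np.column_stack(
        [_numeric(block, c, n, required=True, path=path) for c in ANGLE_COLS]
    )

    origin_angst = np.zeros((3,), float)[None, :].repeat(n, axis=0) if n else np.zeros((0, 3))
    angst = [block.find_values(c) for c in ORIGIN_ANGST_COLS]
    if all(len(a) for a in angst):
        origin_angst = np.column_stack(
            [_numeric(block, c, n, required=True, path=path) for c in ORIGIN_ANGST_COLS]
        )
    else:
        px = [block.find_values(c) for c in ORIGIN_PX_COLS]
        if all(len(p) for p in px):
            origin_angst = pixel_size * np.column_stack(
                [_numeric(block, c, n, required=True, path=path) for c in ORIGIN_PX_COLS]
            )

    positions = coords * float(pixel_size) - origin_angst
    rot, tilt, psi = normalize_euler(angles[:, 0], angles[:, 1], angles[:, 2])

    if tomo_column is None:
        tomo_column = next(
            (c for c in TOMO_COLS if block.find_values(c)), None
        )
    if tomo_column is not None:
        tags = block.find_values(tomo_column)
        if not tags:
            raise StarFormatError(f"{path}: missing tomogram column {tomo_column}")
        tomo = [gemmi.cif.as_string(v) for v in tags]
    else:
        tomo = ["tomo_0"] * n

    data = {
        "particle_id": np.arange(n, dtype=int),
        "tomo_id": tomo,
        "x": positions[:, 0],
        "y": positions[:, 1],
        "z": positions[:, 2],
        "rot": rot,
        "tilt": tilt,
        "psi": psi,
    }
    attached = []
    for col in label_columns:
        tag = col if col.startswith("_") else "_" + col
        vals = block.find_values(tag)
        if not vals:
            raise StarFormatError(f"{path}: missing requested label column {tag}")
        data[tag.lstrip("_")] = [gemmi.cif.as_string(v) for v in vals]
        attached.append(tag.lstrip("_"))

    ps = ParticleSet(
        df=pd.DataFrame(data),
        pixel_size=float(pixel_size),
        provenance=path,
        label_columns=tuple(attached),
    )
    ps.validate()
    return ps


def write_particles(
    particles: ParticleSet,
    path: str | os.PathLike,
    annotations: pd.DataFrame | None = None,
) -> None:
    """Write a particle set (optionally with polysome annotations) as STAR.

    ``annotations`` has columns ``particle_id, polysome_id, chain_position,
    chain_length``; particles not listed receive the sentinel
    ``(-1, -1, 1)``.  Coordinates are written back in pixels (position /
    pixel_size) with no origin columns, so a write/read cycle at the same
    pixel size reproduces positions exactly up to float printing (1e-6 Å).
    """
    df = particles.df
    n = len(df)
    if annotations is not None:
        unknown = set(annotations["particle_id"]) - set(df["particle_id"])
        if unknown:
            raise ValueError(
                f"annotations reference unknown particle_id(s): {sorted(unknown)[:5]}"
            )
        ann = annotations.set_index("particle_id")
        poly_id = np.full(n, UNASSIGNED, int)
        chain_pos = np.full(n, UNASSIGNED, int)
        chain_len = np.ones(n, int)
        idx = ann.index.to_numpy()
        poly_id[idx] = ann["polysome_id"].to_numpy()
        chain_pos[idx] = ann["chain_position"].to_numpy()
        chain_len[idx] = ann["chain_length"].to_numpy()
    else:
        poly_id = chain_pos = chain_len = None

    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = [
        "_rlnTomoName",
        *COORD_COLS,
        *ANGLE_COLS,
        *("_" + c for c in particles.label_columns),
    ]
    if poly_id is not None:
        tags += list(POLYSOME_COLS)
    loop = block.init_loop("", tags)

    px = particles.pixel_size
    for i, row in enumerate(df.itertuples(index=False)):
        cells = [
            str(row.tomo_id),
            f"{row.x / px:.6f}",
            f"{row.y / px:.6f}",
            f"{row.z / px:.6f}",
            f"{row.rot:.6f}",
            f"{row.tilt:.6f}",
            f"{row.psi:.6f}",
            *(gemmi.cif.quote(str(getattr(row, c))) for c in particles.label_columns),
        ]
        if poly_id is not None:
            cells += [str(poly_id[i]), str(chain_pos[i]), str(chain_len[i])]
        loop.add_row(cells)
    doc.write_file(os.fspath(path))
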