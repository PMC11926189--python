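"""Synthetic particle scenes with planted polysome ground truth.

The generator emulates the statistical structure of an in-cell
subtomogram dataset as consumed by the tracing and statistics stages:

* several cells (tomograms), each a box of cytosol;
* planted polysome chains: 3-D paths with bounded turning where each
  successive ribosome is positioned and oriented so that its mapped mRNA
  entry marker sits at a drawn step distance from the predecessor's
  mapped exit marker -- geometrically exact, so recovery tests are exact;
* isolated monosomes with uniformly random orientations, kept clear of
  all other markers by rejection sampling;
* i.i.d. Bernoulli/categorical class labels (bS20 occupancy, Trigger
  Factor binding, functional state) at stated rates;
* Gaussian positional noise.

It does NOT emulate tomographic image formation, missing-wedge effects
or classification errors; labels are exact unless the caller perturbs
them.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ribotrace.pose_geometry import MarkerConfig, map_markers
from ribotrace.star_io import ParticleSet, normalize_euler, write_particles

__all__ = [
    "SceneParams",
    "GroundTruth",
    "SceneCapacityError",
    "simulate_scene",
    "particles_from_poses",
    "emit_fixture_suite",
]


class SceneCapacityError(RuntimeError):
    """Raised when a scene cannot be placed within the attempt budget."""


@dataclass
class SceneParams:
    """Scene-level generator settings.

    Defaults mirror the study conditions the analysis targets: 28 cells,
    a 2xbS20 occupancy of 0.67, Trigger-Factor binding of 0.88, chains of
    mean length ~5 (2 + Poisson(3)), exit-to-entry steps of 70 +- 15 Å
    (well under the 250 Å tracing cut-off), and monosomes kept >= 600 Å
    (> 2x cut-off) from every other marker.
    """

    n_cells: int = 28
    cell_box: tuple[float, float, float] = (12000.0, 12000.0, 5000.0)
    n_polysomes_per_cell: int = 20
    polysome_length_poisson_lam: float = 3.0  # length = 2 + Poisson(lam)
    step_distance_mean: float = 70.0
    step_distance_sd: float = 15.0
    max_turn_deg: float = 60.0
    orientation_jitter_deg: float = 15.0
    monosome_count: int = 400
    monosome_min_clearance: float = 600.0
    chain_clearance: float = 600.0
    occupancy_p: float = 0.67
    tf_bound_p: float = 0.88
    state_probs: dict[str, float] = field(
        default_factory=lambda: {"aa-tRNA": 0.25, "pre-translocation": 0.45, "post-translocation": 0.30}
    )
    position_noise_sd: float = 5.0
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        for p in (self.occupancy_p, self.tf_bound_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        tot = sum(self.state_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")
        if min(self.cell_box) <= 0:
            raise ValueError("cell_box extents must be positive")
        if self.step_distance_mean <= 0:
            raise ValueError("step_distance_mean must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one scene."""

    chains: list[list[int]]  # ordered particle ids, leader first
    step_distances: list[list[float]]
    tomo_of_chain: list[str]

    def true_links(self) -> set[tuple[int, int]]:
        return {
            (c[i], c[i + 1]) for c in self.chains for i in range(len(c) - 1)
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "chains": self.chains,
                    "step_distances": self.step_distances,
                    "tomo_of_chain": self.tomo_of_chain,
                },
                fh,
                indent=1,
            )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    return _unit(rng.normal(size=3))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalised Gaussian quaternion."""
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _cone_direction(rng: np.random.Generator, axis: np.ndarray, half_angle_deg: float) -> np.ndarray:
    """Uniform direction within a cone of given half-angle about ``axis``."""
    cos_max = np.cos(np.radians(half_angle_deg))
    c = rng.uniform(cos_max, 1.0)
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2 * np.pi)
    # orthonormal frame around axis
    a = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, helper))
    e2 = np.cross(a, e1)
    return c * a + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _align_rotation(u: np.ndarray, d: np.ndarray, spin: float) -> np.ndarray:
    """Rotation taking unit vector ``u`` to ``d`` with free spin about u."""
    spin_rot = Rotation.from_rotvec(spin * u).as_matrix()
    axis = np.cross(u, d)
    n = np.linalg.norm(axis)
    dot = float(np.clip(np.dot(u, d), -1.0, 1.0))
    if n < 1e-12:
        if dot > 0:
            align = np.eye(3)
        else:  # antiparallel: rotate 180 deg about any perpendicular
            helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            perp = _unit(np.cross(u, helper))
            align = Rotation.from_rotvec(np.pi * perp).as_matrix()
    else:
        align = Rotation.from_rotvec(np.arccos(dot) * axis / n).as_matrix()
    return align @ spin_rot


def _pose_to_euler(A: np.ndarray, direction: str) -> tuple[float, float, float]:
    """Stored (rot, tilt, psi) such that the mapping matrix equals ``A``."""
    import warnings as _warnings

    R = A if direction == "forward" else A.T
    with _warnings.catch_warnings():
        # at tilt 0/180 the decomposition is non-unique; any valid one works
        _warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
    r, t, p = normalize_euler(np.array([rot]), np.array([tilt]), np.array([psi]))
    return float(r[0]), float(t[0]), float(p[0])


def particles_from_poses(
    positions: np.ndarray,
    pose_matrices: np.ndarray,
    tomo_ids: list[str],
    labels: dict[str, list[str]] | None = None,
    markers: MarkerConfig | None = None,
) -> ParticleSet:
    """Build a :class:`ParticleSet` from explicit mapping matrices.

    ``pose_matrices[i]`` is the matrix A_i with which marker offsets map
    as ``position + A @ offset``; stored Euler angles are derived under
    the marker config's ``map_direction`` (default config if omitted).
    """
    markers = markers or MarkerConfig()
    positions = np.asarray(positions, float)
    n = len(positions)
    eulers = np.array(
        [_pose_to_euler(np.asarray(pose_matrices[i]), markers.map_direction) for i in range(n)]
    ).reshape(n, 3)
    data = {
        "particle_id": np.arange(n, dtype=int),
        "tomo_id": list(tomo_ids),
        "x": positions[:, 0],
        "y": positions[:, 1],
        "z": positions[:, 2],
        "rot": eulers[:, 0],
        "tilt": eulers[:, 1],
        "psi": eulers[:, 2],
    }
    label_cols: tuple[str, ...] = ()
    if labels:
        for k, v in labels.items():
            data[k] = list(v)
        label_cols = tuple(labels)
    return ParticleSet(pd.DataFrame(data), pixel_size=1.0, provenance="synthetic", label_columns=label_cols)


def _draw_step(rng: np.random.Generator, params: SceneParams) -> float:
    for _ in range(1000):
        d = rng.normal(params.step_distance_mean, params.step_distance_sd)
        if d > 1.0:
            return float(d)
    raise SceneCapacityError("step-distance distribution rejects everything > 1 Å")


def _build_chain_geometry(rng: np.random.Generator, params: SceneParams, length: int):
    """Positions, pose matrices and step distances of one planted chain."""
    mk = params.markers
    u = _unit(mk.exit_offset - mk.entry_offset)
    box = np.asarray(params.cell_box, float)
    margin = min(300.0, 0.2 * box.min())
    entry_pt = rng.uniform(margin, box - margin)
    d = _random_unit(rng)
    positions, poses, steps = [], [], []
    for k in range(length):
        d_jit = _cone_direction(rng, d, params.orientation_jitter_deg)
        A = _align_rotation(u, d_jit, spin=rng.uniform(0, 2 * np.pi))
        pos = entry_pt - A @ mk.entry_offset
        positions.append(pos)
        poses.append(A)
        if k < length - 1:
            exit_pt = pos + A @ mk.exit_offset
            step = _draw_step(rng, params)
            d = _cone_direction(rng, d, params.max_turn_deg)
            entry_pt = exit_pt + step * d
            steps.append(step)
    return np.array(positions), poses, steps


def _chain_is_self_consistent(positions, poses, params: SceneParams):
    """Check a (noised) chain against its own markers.

    Returns the list of realized step distances if within the chain each
    exit's nearest entry is its successor (below the trace cut-off) and
    the last exit reaches no chain entry under the cut-off; None otherwise.
    """
    mk = params.markers
    entries = np.array([p + A @ mk.entry_offset for p, A in zip(positions, poses)])
    exits = np.array([p + A @ mk.exit_offset for p, A in zip(positions, poses)])
    n = len(positions)
    dmat = np.linalg.norm(exits[:, None, :] - entries[None, :, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    for i in range(n - 1):
        if np.argmin(dmat[i]) != i + 1 or dmat[i, i + 1] >= mk.trace_cutoff:
            return None
    if n >= 2 and dmat[n - 1].min() < mk.trace_cutoff:
        return None
    return [float(dmat[i, i + 1]) for i in range(n - 1)]


def simulate_scene(params: SceneParams) -> tuple[ParticleSet, GroundTruth]:
    """Generate one multi-cell scene with planted ground truth.

    Deterministic given ``params.seed``.  Raises
    :class:`SceneCapacityError` if rejection sampling cannot place the
    requested content within ``params.max_attempts`` tries.
    """
    rng = np.random.default_rng(params.seed)
    mk = params.markers

    all_pos: list[np.ndarray] = []
    all_pose: list[np.ndarray] = []
    all_tomo: list[str] = []
    gt_chains: list[list[int]] = []
    gt_steps: list[list[float]] = []
    gt_tomo: list[str] = []
    next_id = 0

    for c in range(params.n_cells):
        tomo = f"cell_{c:02d}"
        cell_markers: list[np.ndarray] = []  # entry+exit points placed so far

        def marker_pts(positions, poses):
            pts = []
            for p, A in zip(positions, poses):
                pts.append(p + A @ mk.entry_offset)
                pts.append(p + A @ mk.exit_offset)
            return pts

        def clear_of_existing(pts, clearance) -> bool:
            if not cell_markers:
                return True
            existing = np.asarray(cell_markers)
            for q in pts:
                if np.min(np.linalg.norm(existing - q, axis=1)) < clearance:
                    return False
            return True

        for _ in range(params.n_polysomes_per_cell):
            length = 2 + int(rng.poisson(params.polysome_length_poisson_lam))
            for attempt in range(params.max_attempts):
                positions, poses, _drawn = _build_chain_geometry(rng, params, length)
                # noise applied before the checks so the guarantees hold
                # on the geometry tracing actually sees
                if params.position_noise_sd > 0:
                    positions = positions + rng.normal(
                        0.0, params.position_noise_sd, size=positions.shape
                    )
                box = np.asarray(params.cell_box, float)
                if (positions < 0).any() or (positions > box).any():
                    continue
                steps = _chain_is_self_consistent(positions, poses, params)
                if steps is None:
                    continue
                pts = marker_pts(positions, poses)
                if not clear_of_existing(pts, params.chain_clearance):
                    continue
                break
            else:
                raise SceneCapacityError(
                    f"cell box too small for polysome of length {length} "
                    f"after {params.max_attempts} attempts"
                )
            ids = list(range(next_id, next_id + length))
            next_id += length
            all_pos.extend(positions)
            all_pose.extend(poses)
            all_tomo.extend([tomo] * length)
            cell_markers.extend(pts)
            gt_chains.append(ids)
            gt_steps.append([float(s) for s in steps])
            gt_tomo.append(tomo)

        for _ in range(params.monosome_count):
            for attempt in range(params.max_attempts):
                pos = rng.uniform(0.0, np.asarray(params.cell_box, float))
                if params.position_noise_sd > 0:
                    pos = pos + rng.normal(0.0, params.position_noise_sd, size=3)
                A = _random_rotation(rng)
                pts = marker_pts([pos], [A])
                if clear_of_existing(pts, params.monosome_min_clearance):
                    break
            else:
                raise SceneCapacityError(
                    f"cell box too small for {params.monosome_count} monosomes "
                    f"at clearance {params.monosome_min_clearance} Å"
                )
            all_pos.append(pos)
            all_pose.append(A)
            all_tomo.append(tomo)
            cell_markers.extend(pts)
            next_id += 1

    n = next_id
    positions = np.asarray(all_pos, float).reshape(n, 3)

    states = list(params.state_probs)
    state_p = np.array([params.state_probs[s] for s in states])
    labels = {
        "occupancy": np.where(rng.random(n) < params.occupancy_p, "2xbS20", "1xbS20").tolist(),
        "tf": np.where(rng.random(n) < params.tf_bound_p, "bound", "free").tolist(),
        "state": [states[i] for i in rng.choice(len(states), size=n, p=state_p)],
    }
    particles = particles_from_poses(positions, all_pose, all_tomo, labels, mk)
    truth = GroundTruth(chains=gt_chains, step_distances=gt_steps, tomo_of_chain=gt_tomo)
    return particles, truth


def make_ring_scene(
    n: int = 8,
    markers: MarkerConfig | None = None,
    radius_scale: float = 1.15,
) -> ParticleSet:
    """A symmetric ring of particles whose naive linking forms a cycle.

    Particles sit on a circle, each oriented so its exit faces the next
    particle's entry; every exit-to-entry distance is (numerically) equal,
    so cycle removal must fire exactly once.
    """
    markers = markers or MarkerConfig()
    sep = np.linalg.norm(markers.exit_offset - markers.entry_offset)
    # circumference ~ n * (marker separation + one step length)
    radius = radius_scale * n * sep / (2 * np.pi)
    centre = np.array([radius + 500.0, radius + 500.0, 500.0])
    positions, poses = [], []
    for m in range(n):
        theta = 2 * np.pi * m / n
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        u = _unit(markers.exit_offset - markers.entry_offset)
        A = _align_rotation(u, tangent, spin=0.0)
        pos = centre + radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        positions.append(pos)
        poses.append(A)
    return particles_from_poses(np.array(positions), poses, ["ring"] * n, None, markers)


def emit_fixture_suite(out_dir: str | os.PathLike, seed: int = 0) -> dict[str, str]:
    """Write a graded suite of STAR scenes plus ground-truth JSON.

    Scenes: a hand-checkable 3-particle chain, a tie case where two exits
    share one nearest entry, a symmetric ring forcing a cycle, a
    near-cut-off pair, and a 28-cell study-scale mimic (occupancy 0.67,
    TF 0.88).  Returns a name -> STAR path map.
    """
    out = {}
    os.makedirs(out_dir, exist_ok=True)
    mk = MarkerConfig()
    u = mk.exit_offset - mk.entry_offset

    def save(name, particles, truth: GroundTruth | None):
        path = os.path.join(out_dir, f"{name}.star")
        write_particles(particles, path)
        if truth is not None:
            truth.to_json(os.path.join(out_dir, f"{name}.truth.json"))
        out[name] = path
        return path

    # 3 identity-pose particles along the exit->entry axis, steps 80 and 90 Å
    direction = _unit(u)
    sep = np.linalg.norm(u)
    p0 = np.array([1000.0, 1000.0, 500.0])
    p1 = p0 + (sep + 80.0) * direction
    p2 = p1 + (sep + 90.0) * direction
    # identity mapping matrix: exit of i is `sep + step` from entry of i+1
    tiny = particles_from_poses(
        np.array([p0, p1, p2]), [np.eye(3)] * 3, ["tiny"] * 3, None, mk
    )
    save("tiny_chain", tiny, GroundTruth([[0, 1, 2]], [[80.0, 90.0]], ["tiny"]))

    # shared-neighbour tie: exits of 0 and 1 both exactly 100 Å from the
    # entry of 2, with 0 and 1 oriented so their own entries point away
    e2 = np.array([3000.0, 3000.0, 500.0])
    pos2 = e2 - mk.entry_offset  # identity pose
    rz180 = np.diag([-1.0, -1.0, 1.0])
    pos0 = e2 + np.array([100.0, 0.0, 0.0]) - mk.exit_offset
    pos1 = e2 + np.array([-100.0, 0.0, 0.0]) - rz180 @ mk.exit_offset
    ties = particles_from_poses(
        np.array([pos0, pos1, pos2]), [np.eye(3), rz180, np.eye(3)], ["ties"] * 3, None, mk
    )
    save("shared_tie", ties, None)

    # near-cut-off pair: one just under, one just over the 250 Å cut-off
    q0 = np.array([500.0, 500.0, 500.0])
    q1 = q0 + (sep + mk.trace_cutoff - 1.0) * direction
    q2 = np.array([500.0, 3000.0, 500.0])
    q3 = q2 + (sep + mk.trace_cutoff + 1.0) * direction
    near = particles_from_poses(
        np.array([q0, q1, q2, q3]), [np.eye(3)] * 4, ["near"] * 4, None, mk
    )
    save("near_cutoff", near, GroundTruth([[0, 1]], [[mk.trace_cutoff - 1.0]], ["near"]))

    save("ring_cycle", make_ring_scene(8, mk), None)

    mimic, truth = simulate_scene(SceneParams(seed=seed, markers=mk))
    save("study_mimic", mimic, truth)
    return out
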