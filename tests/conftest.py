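import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from ribotrace.pose_geometry import MarkerConfig
from ribotrace.star_io import ParticleSet
from ribotrace.synthetic import particles_from_poses


@pytest.fixture
def markers() -> MarkerConfig:
    return MarkerConfig()


def random_scene(rng: np.random.Generator, n: int, markers: MarkerConfig,
                 box: float = 600.0, n_tomos: int = 1) -> ParticleSet:
    """n particles with uniform positions and orientations in a box."""
    positions = rng.uniform(0, box, size=(n, 3))
    quats = rng.normal(size=(n, 4))
    poses = Rotation.from_quat(quats / np.linalg.norm(quats, axis=1, keepdims=True)).as_matrix()
    tomos = [f"t{rng.integers(n_tomos)}" for _ in range(n)]
    return particles_from_poses(positions, poses, tomos, None, markers)


def line_chain(markers: MarkerConfig, steps: list[float], origin=(1000.0, 1000.0, 500.0),
               tomo: str = "t0", extra_positions=None) -> ParticleSet:
    """Identity-pose particles in a row so that consecutive exit->entry
    distances equal ``steps``; optional far-away monosome positions."""
    u = markers.exit_offset - markers.entry_offset
    direction = u / np.linalg.norm(u)
    sep = np.linalg.norm(u)
    positions = [np.asarray(origin, float)]
    for s in steps:
        positions.append(positions[-1] + (sep + s) * direction)
    if extra_positions is not None:
        positions.extend(np.asarray(p, float) for p in extra_positions)
    n = len(positions)
    return particles_from_poses(
        np.array(positions), [np.eye(3)] * n, [tomo] * n, None, markers
    )


def labelled_set(labels: dict[str, list[str]], tomo_ids: list[str]) -> ParticleSet:
    """A ParticleSet with trivial geometry, for label-only statistics."""
    n = len(tomo_ids)
    df = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "tomo_id": tomo_ids,
            "x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n),
            "rot": np.zeros(n), "tilt": np.zeros(n), "psi": np.zeros(n),
            **labels,
        }
    )
    return ParticleSet(df, pixel_size=1.0, label_columns=tuple(labels))
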