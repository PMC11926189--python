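"""End-to-end run orchestration: trace -> stats, with an audit trail.

``run_pipeline`` wires the stages over one particle STAR file and writes
every artefact (traced STAR, link CSV, stats JSON, resolved config) into
a run directory, stamped with the package version and a config hash.
Per-rule link-removal counts are logged as JSON lines so the tracing
audit trail is machine-checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

import ribotrace
from ribotrace.pose_geometry import MarkerConfig
from ribotrace.star_io import read_particles, write_particles
from ribotrace.stats import (
    cell_confidence_band,
    compare_strata,
    composition_fractions,
    neighbour_distances,
    occupancy_by_cell,
    state_distribution,
)
from ribotrace.tracer import chains_to_annotations, trace

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    star_path: str
    pixel_size: float
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    label_columns: tuple[str, ...] = ("occupancy", "tf", "state")
    composition_label: str = "occupancy"
    composition_value: str = "2xbS20"
    state_label: str = "state"
    group_label: str = "occupancy"
    distance_bins_A: tuple[float, float, float] = (0.0, 500.0, 25.0)  # start, stop, width
    out_dir: str = "run"
    force: bool = False

    def validate(self) -> None:
        if not os.path.exists(self.star_path):
            raise PipelineError(f"config: input STAR file not found: {self.star_path}")
        if self.pixel_size <= 0:
            raise PipelineError("config: pixel_size must be positive")
        start, stop, width = self.distance_bins_A
        if not (stop > start and width > 0):
            raise PipelineError("config: invalid distance_bins_A")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["markers"]["entry_offset"] = list(self.markers.entry_offset)
        d["markers"]["exit_offset"] = list(self.markers.exit_offset)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _log(fh, **event) -> None:
    fh.write(json.dumps(event, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run trace -> stats and write all artefacts; returns the stats dict.

    Never mutates its inputs; re-running into an existing directory
    requires ``force=True``.
    """
    config.validate()
    out = config.out_dir
    if os.path.exists(os.path.join(out, "stats.json")) and not config.force:
        raise PipelineError(f"output directory {out!r} already populated (use force)")
    os.makedirs(out, exist_ok=True)

    stamp = {"package_version": ribotrace.__version__, "config_hash": config.config_hash()}
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump({**config.resolved(), **stamp}, fh, indent=1)

    log_fh = open(os.path.join(out, "run_log.jsonl"), "w")
    try:
        try:
            particles = read_particles(
                config.star_path, config.pixel_size, config.label_columns
            )
        except Exception as exc:
            raise PipelineError(f"stage read: {exc}") from exc
        _log(log_fh, stage="read", particles=len(particles))

        try:
            chains, graph = trace(particles, config.markers)
        except Exception as exc:
            raise PipelineError(f"stage trace: {exc}") from exc
        _log(log_fh, stage="trace", **graph.audit)

        graph.links.to_csv(os.path.join(out, "links.csv"), index=False)
        write_particles(
            particles, os.path.join(out, "traced.star"), chains_to_annotations(chains)
        )

        try:
            comp = composition_fractions(
                chains, particles, config.composition_label, config.composition_value
            )
            occ = occupancy_by_cell(
                particles, config.composition_label, config.composition_value
            )
            table = neighbour_distances(
                particles, config.markers, config.composition_label
            )
            start, stop, width = config.distance_bins_A
            bins = np.arange(start, stop + width, width)
            band = cell_confidence_band(table, bins)
            strata = compare_strata(table)
            states = state_distribution(particles, config.state_label, config.group_label)
        except Exception as exc:
            raise PipelineError(f"stage stats: {exc}") from exc
        _log(log_fh, stage="stats", distance_rows=len(table), n_cells=occ.n_cells)

        table.to_csv(os.path.join(out, "distance_table.csv"), index=False)
        strata.to_csv(os.path.join(out, "strata_tests.csv"), index=False)
        states["counts"].to_csv(os.path.join(out, "state_counts.csv"))

        stats = {
            **stamp,
            "n_particles": len(particles),
            "n_chains": comp.n_chains,
            "linked_particles": graph.audit.get("linked_particles", 0),
            "composition": {
                "label": comp.label,
                "value": comp.value,
                "mean_across_chains": comp.overall_mean,
                "sd_across_chains": comp.overall_sd,
                "ribosome_weighted_mean": comp.ribosome_weighted_mean,
            },
            "occupancy": {
                "mean_across_cells": occ.mean,
                "sd_across_cells": occ.sd,
                "pooled_fraction": occ.pooled_fraction,
                "n_cells": occ.n_cells,
            },
            "distance_band": {
                "bin_edges_A": band.bin_edges.tolist(),
                "point": band.point.tolist(),
                "lower_5pct": band.lower.tolist(),
                "upper_95pct": band.upper.tolist(),
                "n_cells": band.n_cells,
            },
            "strata_tests": strata.drop(columns=[]).to_dict(orient="records"),
            "state_test": {
                "chi2": states["chi2"],
                "p_value": states["p_value"],
                "dof": states["dof"],
                "notice": states["notice"],
            },
        }
        with open(os.path.join(out, "stats.json"), "w") as fh:
            json.dump(stats, fh, indent=1)
        return stats
    finally:
        log_fh.close()
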