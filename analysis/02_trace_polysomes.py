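#!/usr/bin/env python
"""Trace polysomes in the study-scale mimic and audit the rule firings.

Runs the full pipeline (closest exit-to-entry linking at 25 nm, shortest
shared link, cycle removal, chaining) on the 28-cell scene from
01_simulate_scenes.py, compares the recovered chains against the planted
ground truth, and writes the tracing summary under results/.
"""

import json
from pathlib import Path

from ribotrace.pipeline import RunConfig, run_pipeline
from ribotrace.synthetic import emit_fixture_suite

ROOT = Path(__file__).resolve().parents[1]
SCENES = ROOT / "scratch" / "scenes"
RUN = ROOT / "scratch" / "run_mimic"
RESULTS = ROOT / "results"


def ensure_scenes() -> Path:
    star = SCENES / "study_mimic.star"
    if not star.exists():
        emit_fixture_suite(SCENES, seed=0)
    return star


def main() -> None:
    star = ensure_scenes()
    RESULTS.mkdir(exist_ok=True)
    stats = run_pipeline(RunConfig(star_path=str(star), pixel_size=1.0,
                                   label_columns=("occupancy", "tf", "state"),
                                   out_dir=str(RUN), force=True))
    truth = json.loads((SCENES / "study_mimic.truth.json").read_text())
    log = [json.loads(l) for l in (RUN / "run_log.jsonl").read_text().splitlines()]
    trace_event = next(e for e in log if e["stage"] == "trace")

    recovered = stats["n_chains"]
    planted = len(truth["chains"])
    summary = {
        "n_particles": stats["n_particles"],
        "links_built": trace_event["links_built"],
        "links_removed_shared_rule": trace_event["removed_shared"],
        "links_removed_cycle_rule": trace_event["removed_cycle"],
        "chains_recovered": recovered,
        "chains_planted": planted,
        "linked_particles": stats["linked_particles"],
    }
    (RESULTS / "tracing_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))
    print(f"\nrecovered {recovered}/{planted} planted chains; "
          f"full artefacts in {RUN}")


if __name__ == "__main__":
    main()
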