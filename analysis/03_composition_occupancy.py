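#!/usr/bin/env python
"""Compositional heterogeneity of the traced polysomes.

From the traced study-scale mimic: the per-cell 2xbS20 occupancy (mean
and cell-to-cell SD), the per-polysome 2xbS20 fraction (mean and SD
across chains), the Trigger-Factor bound/free split per ribosome class,
and the functional-state-by-class contingency test.  Tables land in
results/.
"""

import json
from pathlib import Path

import pandas as pd

from ribotrace.star_io import read_particles
from ribotrace.stats import composition_fractions, occupancy_by_cell, state_distribution
from ribotrace.synthetic import SceneParams, emit_fixture_suite
from ribotrace.tracer import trace

ROOT = Path(__file__).resolve().parents[1]
SCENES = ROOT / "scratch" / "scenes"
RESULTS = ROOT / "results"


def main() -> None:
    star = SCENES / "study_mimic.star"
    if not star.exists():
        emit_fixture_suite(SCENES, seed=0)
    RESULTS.mkdir(exist_ok=True)
    markers = SceneParams().markers
    ps = read_particles(star, pixel_size=1.0, label_columns=("occupancy", "tf", "state"))
    chains, _ = trace(ps, markers)

    occ = occupancy_by_cell(ps, "occupancy", "2xbS20")
    comp = composition_fractions(chains, ps, "occupancy", "2xbS20")
    tf = state_distribution(ps, "tf", "occupancy")
    states = state_distribution(ps, "state", "occupancy")

    pd.Series(occ.per_cell, name="fraction_2xbS20").rename_axis("cell").to_csv(
        RESULTS / "occupancy_by_cell.csv")
    pd.Series(comp.per_chain, name="fraction_2xbS20").rename_axis("chain_id").to_csv(
        RESULTS / "composition_by_polysome.csv")
    tf["proportions"].to_csv(RESULTS / "tf_split_by_class.csv")
    states["proportions"].to_csv(RESULTS / "state_distribution_by_class.csv")

    summary = {
        "occupancy_mean_pct": 100 * occ.mean,
        "occupancy_cell_sd_pct": 100 * occ.sd,
        "n_cells": occ.n_cells,
        "polysome_fraction_mean_pct": 100 * comp.overall_mean,
        "polysome_fraction_sd_pct": 100 * comp.overall_sd,
        "n_polysomes": comp.n_chains,
        "tf_bound_pct_by_class": (100 * tf["proportions"]["bound"]).round(2).to_dict(),
        "tf_chi2_p": tf["p_value"],
        "state_chi2_p": states["p_value"],
    }
    (RESULTS / "composition_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))
    print("\nBoth ribosome classes co-occur on the same traced mRNAs; the "
          "per-polysome 2xbS20 fraction mirrors the per-cell occupancy, and "
          "the TF/state splits are class-independent (chi-square p above).")


if __name__ == "__main__":
    main()
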