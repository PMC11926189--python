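"""Compositional and spatial statistics over traced polysomes.

Covers the heterogeneity questions the tracing pipeline feeds:

* per-polysome class composition (e.g. the fraction of 2xbS20 ribosomes
  on each inferred mRNA) with mean/SD across chains,
* per-cell occupancy of a class with mean/SD across cells,
* exit-to-entry distance tables stratified by the (leader, trailer)
  class pair, with cell-to-cell percentile confidence bands,
* pairwise Kolmogorov-Smirnov comparisons between strata (Holm
  corrected), and
* functional-state-by-class contingency analysis (chi-square).

SD convention: population SD (ddof=0) by default for per-cell and
per-chain summaries; pass ``ddof=1`` for the sample convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ribotrace.pose_geometry import MarkerConfig
from ribotrace.star_io import ParticleSet
from ribotrace.tracer import LinkGraph, PolysomeChain, break_cycles, build_links, resolve_shared

__all__ = [
    "CompositionSummary",
    "OccupancySummary",
    "CellCIBand",
    "composition_fractions",
    "occupancy_by_cell",
    "neighbour_distances",
    "cell_confidence_band",
    "compare_strata",
    "state_distribution",
]


@dataclass
class CompositionSummary:
    """Per-chain fraction of members carrying one label value."""

    per_chain: dict[int, float]
    overall_mean: float  # unweighted across chains
    overall_sd: float
    ribosome_weighted_mean: float  # pooled over all chain members
    n_chains: int
    label: str
    value: str


@dataclass
class OccupancySummary:
    """Per-cell fraction of particles carrying one label value."""

    per_cell: dict[str, float]
    mean: float  # cells weighted equally
    sd: float
    pooled_fraction: float  # ribosome-weighted across all cells
    n_cells: int
    label: str
    value: str


@dataclass
class CellCIBand:
    """Per-bin percentile band of per-cell normalised histograms."""

    bin_edges: np.ndarray
    point: np.ndarray  # mean of per-cell densities
    lower: np.ndarray  # 5th percentile across cells
    upper: np.ndarray  # 95th percentile across cells
    pooled: np.ndarray  # single histogram over all cells pooled
    n_cells: int
    degenerate: bool = False


def composition_fractions(
    chains: list[PolysomeChain],
    particles: ParticleSet,
    label: str,
    value: str,
    ddof: int = 0,
) -> CompositionSummary:
    """Fraction of chain members with ``label == value``, per chain.

    The headline mean/SD weight every chain equally regardless of length;
    the ribosome-weighted pooled fraction is reported alongside.
    """
    lab = particles.labels_for(label)
    by_id = dict(zip(particles.df["particle_id"], lab))
    fractions: dict[int, float] = {}
    hits = total = 0
    for c in chains:
        vals = []
        for pid in c.member_ids:
            if pid not in by_id or pd.isna(by_id[pid]):
                raise ValueError(f"particle {pid} lacks label {label!r}")
            vals.append(by_id[pid] == value)
        fractions[c.chain_id] = float(np.mean(vals))
        hits += int(np.sum(vals))
        total += len(vals)
    arr = np.array(list(fractions.values()), float)
    return CompositionSummary(
        per_chain=fractions,
        overall_mean=float(arr.mean()) if len(arr) else float("nan"),
        overall_sd=float(arr.std(ddof=ddof)) if len(arr) else float("nan"),
        ribosome_weighted_mean=hits / total if total else float("nan"),
        n_chains=len(chains),
        label=label,
        value=value,
    )


def occupancy_by_cell(
    particles: ParticleSet,
    label: str,
    value: str,
    ddof: int = 0,
) -> OccupancySummary:
    """Per-cell fraction of particles with ``label == value``.

    Mean and SD weight cells equally; the pooled (ribosome-weighted)
    fraction over all particles is reported alongside.
    """
    lab = particles.labels_for(label)
    hit = (lab == value).astype(float)
    per_cell = hit.groupby(particles.df["tomo_id"]).mean()
    return OccupancySummary(
        per_cell={str(k): float(v) for k, v in per_cell.items()},
        mean=float(per_cell.mean()),
        sd=float(per_cell.std(ddof=ddof)),
        pooled_fraction=float(hit.mean()),
        n_cells=len(per_cell),
        label=label,
        value=value,
    )


def neighbour_distances(
    particles: ParticleSet,
    markers: MarkerConfig,
    label: str,
    cutoff: float | None = None,
    resolved: bool = False,
) -> pd.DataFrame:
    """Exit-to-entry distance of each particle's closest entry neighbour.

    One row per particle with a neighbour under ``cutoff`` (default
    ``markers.distance_cutoff``, the looser 50 nm bound used for
    elongation-style analyses): (tomo_id, from_id, to_id, leader_label,
    trailer_label, distance).  ``resolved=True`` applies the shared-link
    and cycle rules first, restricting rows to surviving polysome links.
    """
    if cutoff is None:
        cutoff = markers.distance_cutoff
    g = build_links(particles, markers, cutoff)
    if resolved:
        g = break_cycles(resolve_shared(g))
    lab = dict(zip(particles.df["particle_id"], particles.labels_for(label)))
    links = g.links
    out = links.assign(
        leader_label=links["from_id"].map(lab),
        trailer_label=links["to_id"].map(lab),
    )
    return out[["tomo_id", "from_id", "to_id", "leader_label", "trailer_label", "distance"]]


def cell_confidence_band(
    table: pd.DataFrame,
    bins: np.ndarray,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> CellCIBand:
    """Percentile band of per-cell distance histograms.

    Each cell's distances are binned and normalised to unit sum; the band
    is the (5th, 95th) percentile of those per-cell curves per bin,
    quantifying cell-to-cell variation.  With fewer than 3 cells the band
    degenerates to the point estimate (with a warning).
    """
    bins = np.asarray(bins, float)
    cells = table.groupby("tomo_id")["distance"]
    curves = []
    for _, d in cells:
        h, _ = np.histogram(d.to_numpy(), bins=bins)
        tot = h.sum()
        curves.append(h / tot if tot else h.astype(float))
    n_cells = len(curves)
    pooled_h, _ = np.histogram(table["distance"].to_numpy(), bins=bins)
    pooled = pooled_h / pooled_h.sum() if pooled_h.sum() else pooled_h.astype(float)
    if n_cells == 0:
        z = np.zeros(len(bins) - 1)
        return CellCIBand(bins, z, z, z, pooled, 0, degenerate=True)
    curves = np.vstack(curves)
    point = curves.mean(axis=0)
    if n_cells < 3:
        warnings.warn(
            f"only {n_cells} cell(s): confidence band degenerates to the point estimate",
            stacklevel=2,
        )
        return CellCIBand(bins, point, point.copy(), point.copy(), pooled, n_cells, True)
    lower = np.percentile(curves, lower_pct, axis=0)
    upper = np.percentile(curves, upper_pct, axis=0)
    return CellCIBand(bins, point, lower, upper, pooled, n_cells)


def compare_strata(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sample KS tests between (leader, trailer) strata.

    Returns one row per stratum pair: sample sizes, medians, KS statistic,
    raw p, Holm-adjusted p and a testable flag (pairs with an empty
    stratum are reported as not testable rather than erroring).  The test
    choice (two-sample KS + Holm) is recorded in ``DataFrame.attrs``.
    """
    strata = {
        (str(a), str(b)): g["distance"].to_numpy()
        for (a, b), g in table.groupby(["leader_label", "trailer_label"])
    }
    names = sorted(strata)
    rows = []
    for s1, s2 in itertools.combinations(names, 2):
        d1, d2 = strata[s1], strata[s2]
        testable = len(d1) > 0 and len(d2) > 0
        if testable:
            res = sps.ks_2samp(d1, d2)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = float("nan"), float("nan")
        rows.append(
            {
                "stratum_a": "-".join(s1),
                "stratum_b": "-".join(s2),
                "n_a": len(d1),
                "n_b": len(d2),
                "median_a": float(np.median(d1)) if len(d1) else float("nan"),
                "median_b": float(np.median(d2)) if len(d2) else float("nan"),
                "ks_statistic": stat,
                "p_value": p,
                "testable": testable,
            }
        )
    report = pd.DataFrame(rows)
    report["p_holm"] = np.nan
    ok = report["testable"].to_numpy(bool) if len(report) else np.array([], bool)
    if ok.any():
        report.loc[ok, "p_holm"] = multipletests(
            report.loc[ok, "p_value"].to_numpy(), alpha=alpha, method="holm"
        )[1]
    report.attrs["test"] = "two-sample Kolmogorov-Smirnov, Holm correction"
    report.attrs["alpha"] = alpha
    return report


def state_distribution(
    particles: ParticleSet,
    state_label: str,
    group_label: str,
) -> dict:
    """Group x state contingency analysis (e.g. TF binding by bS20 class).

    Returns counts, row-normalised proportions, and a chi-square test of
    homogeneity.  Degenerate tables (a single state or group) skip the
    test with a notice; low expected counts (<5) set a validity warning.
    """
    counts = pd.crosstab(
        particles.labels_for(group_label), particles.labels_for(state_label)
    )
    proportions = counts.div(counts.sum(axis=1), axis=0)
    out = {
        "counts": counts,
        "proportions": proportions,
        "chi2": None,
        "p_value": None,
        "dof": None,
        "expected_valid": None,
        "notice": None,
    }
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        out["notice"] = "degenerate table (single group or state); test skipped"
        return out
    chi2, p, dof, expected = sps.chi2_contingency(counts.to_numpy())
    out.update(
        chi2=float(chi2),
        p_value=float(p),
        dof=int(dof),
        expected_valid=bool((expected >= 5).all()),
    )
    if not out["expected_valid"]:
        out["notice"] = "some expected counts < 5; chi-square approximation may be poor"
    return out
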