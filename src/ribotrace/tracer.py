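"""Polysome tracing from directed exit-to-entry link graphs.

Individual mRNA molecules are invisible in cellular tomograms, but two
ribosomes translating the same mRNA hold a constrained relative pose: the
leader's mRNA exit site faces the trailer's mRNA entry site at short
range.  Tracing therefore proceeds in four deterministic stages, applied
per tomogram (one tomogram = one cell; mRNAs cannot span cells):

1. ``build_links`` -- for each particle, the single closest entry site
   among the other particles, kept if closer than the cut-off
   (out-degree <= 1);
2. ``resolve_shared`` -- when several particles point at the same
   neighbour, only the shortest incoming link survives (in-degree <= 1);
3. ``break_cycles`` -- the resulting functional graph can only contain
   simple cycles; each loses its longest link;
4. ``chain`` -- maximal directed paths become polysome chains, ordered
   from the particle with no incoming link.

All ties break on particle_id so the pipeline is fully deterministic.
A link ``i -> j`` means j trails i on the inferred mRNA (i's exit feeds
j's entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ribotrace.pose_geometry import MarkerConfig, map_markers
from ribotrace.star_io import ParticleSet

__all__ = [
    "Link",
    "LinkGraph",
    "PolysomeChain",
    "build_links",
    "resolve_shared",
    "break_cycles",
    "chain",
    "trace",
    "chains_to_annotations",
]

LINK_COLUMNS = ("from_id", "to_id", "distance", "tomo_id")

# brute-force n^2 scan below this many particles per tomogram; above it a
# k-d tree query with exact tie handling gives identical results faster
_BRUTE_FORCE_MAX = 2048


@dataclass(frozen=True)
class Link:
    """Directed exit->entry link between two particles of one tomogram."""

    from_id: int
    to_id: int
    distance: float


@dataclass
class LinkGraph:
    """A set of directed links over a particle set.

    ``links`` is a DataFrame with columns (from_id, to_id, distance,
    tomo_id), sorted by from_id.  ``audit`` accumulates per-rule counts.
    """

    links: pd.DataFrame
    particles: ParticleSet
    audit: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.links)

    def out_degree_ok(self) -> bool:
        return self.links["from_id"].is_unique

    def in_degree_ok(self) -> bool:
        return self.links["to_id"].is_unique

    def successors(self) -> dict[int, int]:
        return dict(zip(self.links["from_id"], self.links["to_id"]))


@dataclass
class PolysomeChain:
    """An ordered run of particles inferred to share one mRNA."""

    chain_id: int
    member_ids: list[int]
    step_distances: list[float]
    tomo_id: str

    @property
    def length(self) -> int:
        return len(self.member_ids)


def _empty_links() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "from_id": pd.Series(dtype=int),
            "to_id": pd.Series(dtype=int),
            "distance": pd.Series(dtype=float),
            "tomo_id": pd.Series(dtype=object),
        }
    )


def _nearest_entry_brute(ids, exits, entries):
    """Per exit, the nearest entry of a *different* particle; ties -> smaller id."""
    d = np.linalg.norm(exits[:, None, :] - entries[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # argmin returns the first (lowest index) minimum; ids are sorted, so
    # the first minimum is the smallest particle_id
    j = np.argmin(d, axis=1)
    return j, d[np.arange(len(ids)), j]


def _nearest_entry_kdtree(ids, exits, entries):
    tree = cKDTree(entries)
    n = len(ids)
    k = min(n, 3)
    dist, idx = tree.query(exits, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best_j = np.empty(n, int)
    best_d = np.empty(n, float)
    for i in range(n):
        cand_j, cand_d = None, np.inf
        for dd, jj in zip(dist[i], idx[i]):
            if jj == i:
                continue
            if dd < cand_d - 1e-12 or (abs(dd - cand_d) <= 1e-12 and (cand_j is None or jj < cand_j)):
                cand_j, cand_d = jj, dd
        if cand_j is None:  # all k hits were self (only possible at tiny n)
            d_all = np.linalg.norm(entries - exits[i], axis=1)
            d_all[i] = np.inf
            cand_j = int(np.argmin(d_all))
            cand_d = d_all[cand_j]
        # exact-tie audit against any equidistant smaller id missed by k
        close = tree.query_ball_point(exits[i], cand_d + 1e-9)
        for jj in close:
            if jj == i:
                continue
            dd = float(np.linalg.norm(entries[jj] - exits[i]))
            if dd < cand_d - 1e-12 or (abs(dd - cand_d) <= 1e-12 and jj < cand_j):
                cand_j, cand_d = jj, dd
        best_j[i], best_d[i] = cand_j, cand_d
    return best_j, best_d


def build_links(
    particles: ParticleSet,
    markers: MarkerConfig,
    cutoff: float | None = None,
) -> LinkGraph:
    """Closest-entry linking: at most one outgoing link per particle.

    For particle i the candidate neighbour j minimises
    ``|exit(i) - entry(j)|`` over all other particles of the same
    tomogram; the link is kept only if that minimum is strictly below
    ``cutoff`` (default: ``markers.trace_cutoff``).
    """
    if cutoff is None:
        cutoff = markers.trace_cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(particles) == 0:
        return LinkGraph(_empty_links(), particles, {"links_built": 0})

    exits_all = map_markers(particles, markers.exit_offset, markers.map_direction)
    entries_all = map_markers(particles, markers.entry_offset, markers.map_direction)
    ids_all = particles.df["particle_id"].to_numpy()
    tomo_all = particles.tomo_ids()

    frames = []
    for tomo in pd.unique(tomo_all):
        sel = np.flatnonzero(tomo_all == tomo)
        if len(sel) < 2:
            continue
        ids = ids_all[sel]
        order = np.argsort(ids)  # tie-break needs ids ascending
        ids, exits, entries = ids[order], exits_all[sel][order], entries_all[sel][order]
        if len(ids) <= _BRUTE_FORCE_MAX:
            j, d = _nearest_entry_brute(ids, exits, entries)
        else:
            j, d = _nearest_entry_kdtree(ids, exits, entries)
        keep = d < cutoff
        frames.append(
            pd.DataFrame(
                {
                    "from_id": ids[keep],
                    "to_id": ids[j[keep]],
                    "distance": d[keep],
                    "tomo_id": tomo,
                }
            )
        )
    links = (
        pd.concat(frames, ignore_index=True).sort_values("from_id", kind="stable").reset_index(drop=True)
        if frames
        else _empty_links()
    )
    return LinkGraph(links, particles, {"links_built": len(links)})


def resolve_shared(graph: LinkGraph) -> LinkGraph:
    """Keep only the shortest incoming link of every shared target.

    Ties break toward the smaller from_id.  Output has in-degree <= 1.
    """
    links = graph.links
    if len(links) == 0:
        return LinkGraph(links.copy(), graph.particles, dict(graph.audit, removed_shared=0))
    ordered = links.sort_values(["to_id", "distance", "from_id"], kind="stable")
    kept = ordered.drop_duplicates("to_id", keep="first")
    kept = kept.sort_values("from_id", kind="stable").reset_index(drop=True)
    audit = dict(graph.audit, removed_shared=len(links) - len(kept))
    return LinkGraph(kept, graph.particles, audit)


def break_cycles(graph: LinkGraph) -> LinkGraph:
    """Remove the longest link of every simple cycle.

    Requires in/out degree <= 1 (a functional graph), where every weak
    component is a path or a simple cycle; removing one link per cycle
    cannot create new cycles.  Ties remove the link with the larger
    from_id.
    """
    links = graph.links
    if not (graph.out_degree_ok() and graph.in_degree_ok()):
        raise ValueError("break_cycles requires in/out degree <= 1")
    succ = graph.successors()
    dist = dict(zip(links["from_id"], links["distance"]))

    drop: set[int] = set()
    colour: dict[int, int] = {}  # 0 in-progress stack, 1 done
    for start in succ:
        if start in colour:
            continue
        path = []
        node = start
        while node in succ and node not in colour:
            colour[node] = 0
            path.append(node)
            node = succ[node]
        if node in colour and colour[node] == 0:
            # found a new cycle: nodes from `node` to end of path
            cyc = path[path.index(node):]
            worst = max(cyc, key=lambda u: (dist[u], u))
            drop.add(worst)
        for u in path:
            colour[u] = 1
        colour[node] = 1

    kept = links[~links["from_id"].isin(drop)].reset_index(drop=True)
    audit = dict(graph.audit, removed_cycle=len(drop))
    return LinkGraph(kept, graph.particles, audit)


def chain(graph: LinkGraph) -> list[PolysomeChain]:
    """Decompose an acyclic degree-<=1 link graph into ordered chains.

    Each maximal directed path becomes one chain ordered from its start
    (the member with no incoming link).  Chain ids are assigned in order
    of the start particle_id; singleton particles are not chains.
    """
    links = graph.links
    if not (graph.out_degree_ok() and graph.in_degree_ok()):
        raise ValueError("chain requires in/out degree <= 1")
    succ = graph.successors()
    dist = dict(zip(links["from_id"], links["distance"]))
    tomo = dict(zip(links["from_id"], links["tomo_id"]))
    has_incoming = set(links["to_id"])

    chains = []
    visited: set[int] = set()
    for start in sorted(succ):
        if start in has_incoming:
            continue
        members = [start]
        steps = []
        node = start
        while node in succ:
            steps.append(float(dist[node]))
            node = succ[node]
            members.append(node)
        visited.update(members)
        chains.append(
            PolysomeChain(
                chain_id=len(chains),
                member_ids=members,
                step_distances=steps,
                tomo_id=str(tomo[start]),
            )
        )
    if len(visited) < len(set(succ) | has_incoming):
        raise ValueError("cycle encountered; run break_cycles first")
    return chains


def trace(
    particles: ParticleSet,
    markers: MarkerConfig,
    cutoff: float | None = None,
) -> tuple[list[PolysomeChain], LinkGraph]:
    """Full tracing pipeline: build -> resolve shared -> break cycles -> chain.

    Returns the chains and the final (resolved, acyclic) link graph; the
    graph's ``audit`` dict records how many links each rule removed.
    """
    g = build_links(particles, markers, cutoff)
    g = resolve_shared(g)
    g = break_cycles(g)
    chains = chain(g)
    g.audit["chains"] = len(chains)
    g.audit["linked_particles"] = int(sum(c.length for c in chains))
    return chains, g


def chains_to_annotations(chains: list[PolysomeChain]) -> pd.DataFrame:
    """Per-particle (polysome_id, chain_position, chain_length) table."""
    rows = [
        (pid, c.chain_id, pos, c.length)
        for c in chains
        for pos, pid in enumerate(c.member_ids)
    ]
    return pd.DataFrame(
        rows, columns=["particle_id", "polysome_id", "chain_position", "chain_length"]
    )
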