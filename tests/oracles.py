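"""Independent brute-force implementations of the tracing rules.

Deliberately naive (pure-python loops over explicit point lists) so they
share no code path with ribotrace.tracer; used as oracles in equivalence
tests.  Link = (from_id, to_id, distance).
"""

from __future__ import annotations

import math


def bf_build(ids, tomos, exits, entries, cutoff):
    """For each particle, the closest other entry in the same tomogram."""
    links = []
    for i, pid in enumerate(ids):
        best = None
        for j, qid in enumerate(ids):
            if i == j or tomos[i] != tomos[j]:
                continue
            d = math.dist(exits[i], entries[j])
            if best is None or d < best[1] or (d == best[1] and qid < best[0]):
                best = (qid, d)
        if best is not None and best[1] < cutoff:
            links.append((pid, best[0], best[1]))
    return links


def bf_resolve(links):
    """Keep only the shortest incoming link per target (ties: smaller from)."""
    by_target = {}
    for f, t, d in links:
        cur = by_target.get(t)
        if cur is None or d < cur[1] or (d == cur[1] and f < cur[0]):
            by_target[t] = (f, d)
    return [(f, t, d) for t, (f, d) in by_target.items()]


def bf_break_cycles(links):
    """Remove the longest link of every simple cycle (ties: larger from)."""
    succ = {f: (t, d) for f, t, d in links}
    removed = set()
    seen = set()
    for start in list(succ):
        if start in seen:
            continue
        path, node = [], start
        while node in succ and node not in seen and node not in path:
            path.append(node)
            node = succ[node][0]
        if node in path:  # cycle from `node` onwards
            cyc = path[path.index(node):]
            worst = max(cyc, key=lambda u: (succ[u][1], u))
            removed.add(worst)
        seen.update(path)
    return [(f, t, d) for f, t, d in links if f not in removed]


def bf_chains(links):
    """Maximal directed paths, each ordered from its start node."""
    succ = {f: t for f, t, _ in links}
    has_in = {t for _, t, _ in links}
    chains = []
    for start in sorted(succ):
        if start in has_in:
            continue
        members, node = [start], start
        while node in succ:
            node = succ[node]
            members.append(node)
        chains.append(members)
    return chains


def bf_trace(ids, tomos, exits, entries, cutoff):
    return bf_chains(bf_break_cycles(bf_resolve(bf_build(ids, tomos, exits, entries, cutoff))))
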