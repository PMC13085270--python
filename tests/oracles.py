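"""Independent brute-force oracles used to validate the fast paths.

The DCJ oracle does breadth-first search over adjacency-set states under
all double-cut-and-join moves (including ones creating circular
intermediates), so it is a genuinely independent check of the
closed-form distance.  Bidirectional search keeps it tractable up to 5
contigs.
"""

from __future__ import annotations

from itertools import combinations

from scafeval.layout import GenomeLayout, layout_to_adjacencies

State = frozenset  # of frozenset({extremity, extremity})


def _universe(layout: GenomeLayout) -> frozenset:
    return frozenset(
        (cid, end) for cid in layout.contig_ids() for end in ("head", "tail")
    )


def _successors(state: State, universe: frozenset) -> set[State]:
    adjacencies = list(state)
    paired = set()
    for adj in adjacencies:
        paired |= adj
    telomeres = sorted(universe - paired)
    out: set[State] = set()
    base = set(state)
    # two adjacencies -> two recombinations
    for a, b in combinations(adjacencies, 2):
        p, q = tuple(a)
        r, s = tuple(b)
        rest = base - {a, b}
        out.add(frozenset(rest | {frozenset((p, r)), frozenset((q, s))}))
        out.add(frozenset(rest | {frozenset((p, s)), frozenset((q, r))}))
    # adjacency + telomere
    for a in adjacencies:
        p, q = tuple(a)
        rest = base - {a}
        for t in telomeres:
            out.add(frozenset(rest | {frozenset((p, t))}))
            out.add(frozenset(rest | {frozenset((q, t))}))
        # cut: adjacency -> two telomeres
        out.add(frozenset(rest))
    # two telomeres -> adjacency
    for t1, t2 in combinations(telomeres, 2):
        out.add(frozenset(base | {frozenset((t1, t2))}))
    return out


def dcj_distance_bfs_uni(
    assembly: GenomeLayout, reference: GenomeLayout
) -> int:
    """Plain single-direction BFS; only tractable for tiny contig sets."""
    if assembly.contig_ids() != reference.contig_ids():
        raise ValueError("layouts must share one contig set")
    universe = _universe(assembly)
    src: State = frozenset(layout_to_adjacencies(assembly).adjacencies)
    dst: State = frozenset(layout_to_adjacencies(reference).adjacencies)
    if src == dst:
        return 0
    seen = {src}
    frontier = {src}
    depth = 0
    while frontier:
        depth += 1
        nxt = set()
        for state in frontier:
            for succ in _successors(state, universe):
                if succ == dst:
                    return depth
                if succ not in seen:
                    seen.add(succ)
                    nxt.add(succ)
        frontier = nxt
    raise AssertionError("target unreachable")


def dcj_distance_bfs(assembly: GenomeLayout, reference: GenomeLayout) -> int:
    """Exact DCJ distance by bidirectional breadth-first search."""
    if assembly.contig_ids() != reference.contig_ids():
        raise ValueError("layouts must share one contig set")
    universe = _universe(assembly)
    src: State = frozenset(layout_to_adjacencies(assembly).adjacencies)
    dst: State = frozenset(layout_to_adjacencies(reference).adjacencies)
    if src == dst:
        return 0
    front_a: dict[State, int] = {src: 0}
    front_b: dict[State, int] = {dst: 0}
    edge_a: set[State] = {src}
    edge_b: set[State] = {dst}
    depth_a = depth_b = 0
    while True:
        # expand the smaller frontier
        if len(edge_a) <= len(edge_b):
            edge, seen, other, depth_a = edge_a, front_a, front_b, depth_a + 1
            new_depth = depth_a
        else:
            edge, seen, other, depth_b = edge_b, front_b, front_a, depth_b + 1
            new_depth = depth_b
        nxt: set[State] = set()
        best = None
        for state in edge:
            for succ in _successors(state, universe):
                if succ in other:
                    cand = new_depth + other[succ]
                    best = cand if best is None else min(best, cand)
                if succ not in seen:
                    seen[succ] = new_depth
                    nxt.add(succ)
        if best is not None:
            return best
        if not nxt:
            raise AssertionError("search space exhausted without meeting")
        if edge is edge_a:
            edge_a = nxt
        else:
            edge_b = nxt
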