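"""Contig generation from a unitig graph and read paths.

The pipeline is: count per-edge read support, drop transitive edges that
have a well-supported longer detour, run a modified breadth-first search
that records which edges a careful assembler would walk (with per-node
visit budgets of floor((id+od)/2)), then a depth-first pass over the
traversed edges that emits contigs, cutting at unresolvable branching
nodes. A branching node revisited inside a single walk closes a loop and
is considered resolved: its cut flag is removed, so simple repeat loops
are emitted as one contig rather than shattered.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .io import OrientedNode, ReadPath, SequenceRecord, UnitigGraph, revcomp

DEFAULT_MIN_SUPPORT = 2
MAX_TRANSITIVE_HOPS = 5


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _mirror_step(s: OrientedNode) -> OrientedNode:
    return (s[0], _flip(s[1]))


# ---------------------------------------------------------------------------
# support and components


def count_edge_support(graph: UnitigGraph, read_paths: list[ReadPath]) -> UnitigGraph:
    """Return a copy of the graph with per-edge support = number of path
    steps traversing the edge (a path crossing an edge twice counts twice)."""
    g = graph.copy()
    g.support = {k: 0 for k in g.support}
    for path in read_paths:
        for a, b in zip(path.steps, path.steps[1:]):
            if not g.has_edge(a, b):
                raise ValueError(
                    f"path {path.read_id} steps over non-edge {a}->{b}"
                )
            g.add_support(a, b)
    return g


def component_labels(graph: UnitigGraph) -> dict[str, int]:
    """Connected-component label per node on the undirected skeleton."""
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _ in graph.edges():
        ru, rv = find(u[0]), find(v[0])
        if ru != rv:
            parent[ru] = rv
    roots = sorted({find(n) for n in graph.nodes})
    index = {r: i for i, r in enumerate(roots)}
    return {n: index[find(n)] for n in graph.nodes}


# ---------------------------------------------------------------------------
# transitive edges


def _has_detour(graph: UnitigGraph, u: OrientedNode, v: OrientedNode,
                min_support: int | None, max_hops: int) -> bool:
    """Is there a path u -> ... -> v of >= 2 edges avoiding the direct edge,
    optionally requiring support >= min_support on every edge?"""
    frontier = deque()
    for w in graph.successors(u):
        if w == v:
            continue
        if min_support is not None and graph.get_support(u, w) < min_support:
            continue
        frontier.append((w, 1))
    seen = {u}
    while frontier:
        node, depth = frontier.popleft()
        if node in seen or depth > max_hops:
            continue
        seen.add(node)
        for w in graph.successors(node):
            if min_support is not None and graph.get_support(node, w) < min_support:
                continue
            if w == v:
                return True
            frontier.append((w, depth + 1))
    return False


def remove_transitive_edges(graph: UnitigGraph,
                            min_support: int = DEFAULT_MIN_SUPPORT,
                            max_hops: int = MAX_TRANSITIVE_HOPS) -> UnitigGraph:
    """Remove every well-supported direct edge u->v shadowed by a longer
    path u->o->...->v whose edges all have support >= min_support."""
    g = graph.copy()
    for u, v, _ in sorted(graph.edges()):
        if g.get_support(u, v) < min_support:
            continue
        if not g.has_edge(u, v):
            continue
        if _has_detour(g, u, v, min_support, max_hops):
            g.remove_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# modified BFS


@dataclass
class BfsTraversal:
    """The subset of edges walked by the modified BFS, with per-visit order
    numbers and timestamps."""

    graph: UnitigGraph
    edges: set[tuple[OrientedNode, OrientedNode]] = field(default_factory=set)
    visits: dict[OrientedNode, list[int]] = field(default_factory=dict)  # timestamps
    budget: dict[OrientedNode, int] = field(default_factory=dict)

    def first_timestamp(self, node: OrientedNode) -> int:
        ts = self.visits.get(node)
        return ts[0] if ts else 1 << 60

    def out_edges(self, node: OrientedNode) -> list[OrientedNode]:
        return sorted(v for (u, v) in self.edges if u == node)


def _budgets(graph: UnitigGraph) -> dict[OrientedNode, int]:
    out = {}
    for n in graph.nodes:
        deg = graph.in_degree(n) + graph.out_degree(n)
        b = max(1, deg // 2)
        out[(n, "+")] = b
        out[(n, "-")] = b
    return out


def modified_bfs(graph: UnitigGraph,
                 min_support: int = DEFAULT_MIN_SUPPORT) -> BfsTraversal:
    """BFS from zero-indegree oriented nodes with three branching rules:
    a successor reachable by a longer path through a sibling is deferred
    (transitive, rule 2); otherwise the single best-supported successor with
    support >= min_support is taken (rule 3); if none reaches min_support,
    all remaining successors are taken (rule 4). Each oriented node may be
    visited floor((id+od)/2) times (minimum 1); deferred successors get
    their chance on later visits. Nodes left unvisited (isolated or cyclic
    components) are re-seeded, longest node first."""
    trav = BfsTraversal(graph, budget=_budgets(graph))
    visits: dict[OrientedNode, int] = {}
    taken_from: dict[OrientedNode, set[OrientedNode]] = {}
    clock = 0

    indeg: dict[OrientedNode, int] = {}
    for n in graph.nodes:
        for o in "+-":
            indeg[(n, o)] = 0
    for n in graph.nodes:
        for o in "+-":
            for w in graph.successors((n, o)):
                indeg[w] += 1

    def visit(node: OrientedNode):
        nonlocal clock
        clock += 1
        visits[node] = visits.get(node, 0) + 1
        trav.visits.setdefault(node, []).append(clock)

    def run(queue: deque):
        nonlocal clock
        while queue:
            v = queue.popleft()
            succ = [w for w in graph.successors(v)
                    if w not in taken_from.setdefault(v, set())]
            if not succ:
                continue
            # rule 2: defer successors shadowed by a longer path via a sibling
            # (a legitimate detour may not revisit the branching node itself)
            plain, deferred = [], []
            for w in succ:
                shadowed = False
                for o in graph.successors(v):
                    if o == w:
                        continue
                    if o == _mirror_step(w):
                        continue
                    if _has_detour_from(graph, o, w, MAX_TRANSITIVE_HOPS,
                                        forbidden=v):
                        shadowed = True
                        break
                (deferred if shadowed else plain).append(w)
            pool = plain if plain else deferred
            strong = [w for w in pool if graph.get_support(v, w) >= min_support]
            if strong:
                # rule 3: single best-supported successor this visit
                chosen = [max(strong, key=lambda w: (graph.get_support(v, w),
                                                     graph.node_len(w[0]), w))]
            else:
                # rule 4: no successor is convincing, take them all
                chosen = pool
            for w in chosen:
                taken_from[v].add(w)
                trav.edges.add((v, w))
                if visits.get(w, 0) < trav.budget[w]:
                    visit(w)
                    queue.append(w)

    seeds = sorted(
        (n, o) for n in graph.nodes for o in "+-"
        if indeg[(n, o)] == 0 and graph.successors((n, o))
    )
    queue: deque = deque()
    for s in seeds:
        visit(s)
        queue.append(s)
    run(queue)

    # re-seed anything never visited in either orientation
    while True:
        left = [n for n in graph.nodes
                if not visits.get((n, "+")) and not visits.get((n, "-"))]
        if not left:
            break
        seed = (max(left, key=lambda n: (graph.node_len(n), n)), "+")
        visit(seed)
        run(deque([seed]))
    return trav


def _has_detour_from(graph: UnitigGraph, start: OrientedNode,
                     target: OrientedNode, max_hops: int,
                     forbidden: OrientedNode | None = None) -> bool:
    """Reachability start -> ... -> target within max_hops edges, never
    stepping through `forbidden`."""
    if start == target:
        return False
    frontier = deque([(start, 0)])
    seen = set()
    while frontier:
        node, depth = frontier.popleft()
        if node in seen or depth >= max_hops:
            continue
        seen.add(node)
        for w in graph.successors(node):
            if w == forbidden:
                continue
            if w == target:
                return True
            frontier.append((w, depth + 1))
    return False


# ---------------------------------------------------------------------------
# DFS and contig emission


@dataclass
class Contig:
    """An ordered oriented walk through the unitig graph plus its sequence."""

    id: str
    steps: list[OrientedNode]
    component: int = 0
    seq: str = ""

    def __len__(self) -> int:
        return len(self.seq)


def _cut_flags(trav: BfsTraversal) -> dict[str, str]:
    """Cut flags per branching node from the traversal-graph degrees (edges
    the BFS declined to walk cannot make a node unresolvable): 1-in/many-out
    cuts outgoing, many-in/1-out cuts incoming, many/many cuts everything."""
    indeg: dict[str, set] = {}
    outdeg: dict[str, set] = {}
    for u, w in trav.edges:
        if u[1] == "+":
            outdeg.setdefault(u[0], set()).add(w)
        else:
            indeg.setdefault(u[0], set()).add((w[0], _flip(w[1])))
        if w[1] == "+":
            indeg.setdefault(w[0], set()).add(u)
        else:
            outdeg.setdefault(w[0], set()).add((u[0], _flip(u[1])))
    flags = {}
    for n in trav.graph.nodes:
        i = len(indeg.get(n, ()))
        o = len(outdeg.get(n, ()))
        if i <= 1 and o <= 1:
            continue
        if i <= 1 and o > 1:
            flags[n] = "out"
        elif i > 1 and o <= 1:
            flags[n] = "in"
        else:
            flags[n] = "both"
    return flags


def dfs_contigs(trav: BfsTraversal) -> list[Contig]:
    """Walk the BFS-traversal edges depth-first (earliest BFS timestamp
    first, within visit budgets), clear the cut flag of any node whose
    revisit closes a loop inside one walk, then sever the walks at the
    remaining flags and emit each maximal unsevered path as a contig."""
    graph = trav.graph
    flags = _cut_flags(trav)
    budget = trav.budget
    visits: dict[OrientedNode, int] = {}
    used_edges: set[tuple[OrientedNode, OrientedNode]] = set()

    def walk_from(start: OrientedNode) -> list[OrientedNode]:
        path = [start]
        on_path = {start}
        visits[start] = visits.get(start, 0) + 1
        cur = start
        while True:
            options = [
                w for w in trav.out_edges(cur)
                if (cur, w) not in used_edges and visits.get(w, 0) < budget[w]
            ]
            if not options:
                break
            nxt = min(options, key=lambda w: (trav.first_timestamp(w), w))
            used_edges.add((cur, nxt))
            if nxt in on_path:
                flags.pop(nxt[0], None)  # loop closed: the node is resolved
            visits[nxt] = visits.get(nxt, 0) + 1
            path.append(nxt)
            on_path.add(nxt)
            cur = nxt
        return path

    ordered = sorted(trav.visits, key=lambda n: trav.first_timestamp(n))
    walks = []
    for node in ordered:
        while visits.get(node, 0) < budget[node] and (
            visits.get(node, 0) == 0
            or any((node, w) not in used_edges and visits.get(w, 0) < budget[w]
                   for w in trav.out_edges(node))
        ):
            before = visits.get(node, 0)
            walks.append(walk_from(node))
            if visits.get(node, 0) == before:  # safety: no progress
                break

    # sever at remaining flags; a flag names the node's forward-orientation
    # side, so a minus-orientation step uses the opposite side
    def cut_between(u: OrientedNode, w: OrientedNode) -> bool:
        side_u = "out" if u[1] == "+" else "in"
        side_w = "in" if w[1] == "+" else "out"
        fu, fw = flags.get(u[0]), flags.get(w[0])
        return fu in (side_u, "both") or fw in (side_w, "both")

    segments: list[list[OrientedNode]] = []
    for walk in walks:
        seg = [walk[0]]
        for u, w in zip(walk, walk[1:]):
            if cut_between(u, w):
                segments.append(seg)
                seg = [w]
            else:
                seg.append(w)
        segments.append(seg)

    # deduplicate mirror-orientation duplicates
    chosen: dict[tuple, list[OrientedNode]] = {}
    for seg in segments:
        mirror = [_mirror_step(s) for s in reversed(seg)]
        key = min(tuple(seg), tuple(mirror))
        if key in chosen:
            continue
        plus = sum(1 for _, o in seg if o == "+")
        plus_m = len(seg) - plus
        rep = seg if (plus, tuple(mirror)) >= (plus_m, tuple(seg)) else mirror
        chosen[key] = rep

    # forward and mirror traversals can decompose a component differently;
    # drop walks whose every node-visit is already consumed by longer ones
    remaining = {n: budget[(n, "+")] for n in graph.nodes}
    kept_steps = []
    for steps in sorted(chosen.values(), key=lambda s: (-len(s), s)):
        novel = any(remaining[n] > 0 for n, _ in steps)
        if not novel:
            continue
        for n, _ in steps:
            if remaining[n] > 0:
                remaining[n] -= 1
        kept_steps.append(steps)

    contigs = []
    labels = component_labels(graph)
    for i, steps in enumerate(sorted(kept_steps)):
        contigs.append(Contig(f"contig_{i + 1}", steps, labels[steps[0][0]]))
    return contigs


def contig_sequence(contig: Contig, graph: UnitigGraph) -> SequenceRecord:
    """Concatenate node sequences along the walk, trimming edge overlaps and
    reverse-complementing minus-orientation nodes."""

    def oriented_seq(step: OrientedNode) -> str:
        s = graph.nodes[step[0]]
        return s if step[1] == "+" else revcomp(s)

    parts = [oriented_seq(contig.steps[0])]
    for u, v in zip(contig.steps, contig.steps[1:]):
        ov = graph.overlap(u, v) if graph.has_edge(u, v) else 0
        s = oriented_seq(v)
        if ov > len(s):
            raise ValueError(
                f"overlap {ov} longer than node {v[0]} ({len(s)} bp)"
            )
        parts.append(s[ov:])
    return SequenceRecord(contig.id, "".join(parts))


def assemble_contigs(graph: UnitigGraph, read_paths: list[ReadPath],
                     min_support: int = DEFAULT_MIN_SUPPORT) -> list[Contig]:
    """Full contig stage: support counting, transitive-edge removal,
    modified BFS, DFS emission, and sequence construction."""
    supported = count_edge_support(graph, read_paths)
    simplified = remove_transitive_edges(supported, min_support)
    trav = modified_bfs(simplified, min_support)
    contigs = dfs_contigs(trav)
    for c in contigs:
        c.seq = contig_sequence(c, simplified).seq
    return contigs
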