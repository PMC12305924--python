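"""Turn a unitig graph plus read paths into contigs.

Edge support is counted from the read paths, transitive shortcuts with a
well-supported longer detour are removed, and the modified BFS + DFS
resolve loops: a branching node revisited inside one walk is considered
solved and emitted within a single contig.
"""

from tandemfill.graph import assemble_contigs
from tandemfill.io import ReadPath, UnitigGraph

# the published worked example: E -> A -> B -> C -> A -> D is one contig
g = UnitigGraph()
for n, seq in zip("EABCD", ("ACGTACGTAC", "TTGGCCAATT", "GGGTTTAAAC",
                            "CCCGGGTTTA", "AATTCCGGAA")):
    g.add_node(n, seq)
for u, v in [("E", "A"), ("A", "B"), ("B", "C"), ("C", "A"), ("A", "D")]:
    g.add_edge(u, "+", v, "+", 0)
# reads thread the duplicated segment twice, so the loop edges carry more
# support than the A -> D exit; the BFS therefore walks the loop first
paths = [ReadPath(f"r{i}", [("E", "+"), ("A", "+"), ("B", "+")])
         for i in range(3)]
paths += [ReadPath(f"s{i}", [("B", "+"), ("C", "+"), ("A", "+")])
          for i in range(3)]
paths += [ReadPath(f"t{i}", [("A", "+"), ("D", "+")]) for i in range(2)]

contigs = assemble_contigs(g, paths, min_support=2)
for c in contigs:
    walk = "->".join(n for n, _ in c.steps)
    print(f"{c.id}: {walk} ({len(c.seq)} bp)")
# A is visited twice (budget floor((2+2)/2) = 2); the loop B->C->A clears
# its cut flag, so the repeat is traversed instead of shattered.
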