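"""Overlapping communities on a regular 8x8 lattice.

A lattice has no modular structure, which makes it a clean illustration of
how link partitioning turns an edge clustering into overlapping node
communities: the exact k-median optimum on the line graph splits the 112
edges into four equal pinwheel-shaped clusters, and nodes on the seams
share their incident edges between two clusters.  At the default threshold
θ=0.5 each node keeps its majority cluster only; lowering θ to 0.3 admits
the seam nodes (belonging fraction 1/3) into both neighbouring communities,
so each community overlaps exactly two others.
"""

import itertools

import lpam

g = lpam.grid_graph(8, 8)
print(f"8x8 lattice: {g.n} nodes, {g.m} edges")

for theta in (0.5, 0.3):
    res = lpam.run_lpam(g, k=4, distance="cm", solver="exact", theta=theta)
    sizes = [len(c) for c in res.cover.communities]
    overlaps = {
        (i, j): len(res.cover.communities[i] & res.cover.communities[j])
        for i, j in itertools.combinations(range(4), 2)
        if res.cover.communities[i] & res.cover.communities[j]}
    print(f"\nk=4, theta={theta}: objective={res.objective:.2f}")
    print(f"  medoid edges: {res.medoid_edges}")
    print(f"  community sizes: {sizes}  (equal => symmetric solution)")
    print(f"  overlapping pairs: {overlaps or 'none'}")
    print(f"  unassigned nodes: {len(res.cover.unassigned)}")

res2 = lpam.run_lpam(g, k=2, distance="cm", theta=0.3)
c0, c1 = res2.cover.communities
print(f"\nk=2, theta=0.3: sizes {len(c0)}/{len(c1)}, "
      f"overlap {len(c0 & c1)} nodes (two equal overlapping halves)")
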