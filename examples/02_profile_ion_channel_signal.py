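"""Profile a punctate signal channel along a reconstructed skeleton.

Places ten fluorescent puncta at known arc positions along a straight tube,
adds shot noise, and measures the point / mean-in-sphere / max-in-sphere
datasets at every compartment of the reconstructed skeleton.
"""

import numpy as np

import arbormap as am

fx = am.standard_fixtures(["straight_tube"])["straight_tube"]
geometry = fx.morphology.geometry
mask = am.remove_small_components(am.segment(fx.morphology))
graph = am.estimate_radius(
    am.build_graph(am.extract_midline(mask), fx.seed_point, geometry,
                   mask=mask), mask)

true_arcs = np.linspace(2.0, 18.0, 10)
puncta = [am.PunctumSpec("trunk", a, amplitude=180.0, sigma=0.3)
          for a in true_arcs]
signal = am.render_signal(puncta, fx.truth, geometry, baseline=20.0,
                          noise=am.NoiseModel(gaussian_sigma=4.0,
                                              poisson=True), seed=99)

records = am.profile_graph(graph, signal, am.SphereWindow(diameter=6.0))
path = am.select_path(graph, [graph.edges[0].name], records)
am.write_profile_txt(path, "dendrite_profile.txt")
am.write_spatial_graph(graph, records, "profile.am", mode="filament")

rows = path.records
print(f"{len(rows)} compartments along {rows[-1].arc_length:.1f} um")
print("arc_um  point  mean   max")
for r in rows[:: len(rows) // 10]:
    print(f"{r.arc_length:6.2f} {r.point_value:6.0f} {r.mean_value:6.1f} "
          f"{r.max_value:5.0f}")
# Point values spike near the true punctum positions (baseline ~20 gray
# levels between them); the 6-um-sphere mean varies smoothly. The txt file
# loads directly as tab-separated waves; profile.am opens in Amira-class
# viewers as a colored filament.
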