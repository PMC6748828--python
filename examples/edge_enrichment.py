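"""Edge enrichment and edge colocalisation of a membrane-marker volume.

Generates an intensity volume around a box cell whose longitudinal edges
carry twice the marker signal of transverse edges, then recovers the
per-edge relative enrichment; also demonstrates Manders colocalisation with
the 10% occupancy exclusion rule.
"""

import numpy as np

from wallmech.morphometrics import (edge_enrichment,
                                    manders_edge_colocalisation)
from wallmech.synthetic import make_colocalised_pair, make_edge_intensity_cell

vol, mask, edges, truth = make_edge_intensity_cell(
    edge_ratios={"longitudinal": 2.0, "transverse": 1.0},
    noise_sd=0.05, seed=1)
rep = edge_enrichment(vol, mask, edges, voxel_size=0.25)

print("relative enrichment by edge class (1 = cell edge average):")
print(f"  longitudinal edges: {rep.class_mean('longitudinal'):.3f}")
print(f"  transverse edges:   {rep.class_mean('transverse'):.3f}")
print("The generator laid down a 2:1 longitudinal:transverse signal; the")
print("recovered class means preserve that ratio after normalisation.")
print()

a, b, t = make_colocalised_pair(overlap=0.5, occupancy_a=0.3,
                                occupancy_b=0.3, seed=2)
coloc = manders_edge_colocalisation(a, b, np.ones(a.shape, dtype=bool))
print(f"Manders M1 = {coloc.M1:.3f}, M2 = {coloc.M2:.3f} "
      f"(designed overlap {t.overlap})")
a, b, _ = make_colocalised_pair(overlap=1.0, occupancy_a=0.05,
                                occupancy_b=0.5, seed=3)
coloc = manders_edge_colocalisation(a, b, np.ones(a.shape, dtype=bool))
print(f"sparse channel (5% occupancy): excluded = {coloc.excluded} "
      "(10% rule)")
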