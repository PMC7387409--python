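"""Quantify periphery-to-core infiltration with the spatial kurtosis.

Compares a uniformly infiltrated field with a core-concentrated one: the
Pearson kurtosis K = m4/m2^2 of the periphery->core (x) coordinate rises
when cells pile up toward the core. Also demonstrates the vessel/cell count
correlation on synthetic immunofluorescence fields.
"""

from ivmotility import (
    draw_depth_positions, generate_spatial_mask, generate_vessel_fields,
    mask_positions, spatial_kurtosis, vessel_cell_correlation,
)

x_uniform = draw_depth_positions(20_000, ("uniform",), width=1000.0, seed=0)
x_core = draw_depth_positions(20_000, ("beta", 5, 1.5), width=1000.0, seed=0)
print(f"K uniform infiltration: {spatial_kurtosis(x_uniform):.3f}  (theory 1.8)")
print(f"K core-concentrated:    {spatial_kurtosis(x_core):.3f}  (> uniform)")

mask, true_pos = generate_spatial_mask(120, ("beta", 5, 1.5), field=(768, 768), seed=1)
pos = mask_positions(mask)
print(f"\nbinary mask: {len(pos)} components recovered from {len(true_pos)} "
      f"placed cells; K from mask centroids = {spatial_kurtosis(pos):.3f}")

fields = generate_vessel_fields(200, target_rho=0.7, seed=2)
rho, p = vessel_cell_correlation(fields)
print(f"\nvessel vs cell counts over {len(fields)} fields: "
      f"Spearman rho = {rho:.3f} (target 0.7), p = {p:.2e}")
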