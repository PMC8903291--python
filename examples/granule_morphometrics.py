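"""Granules: detect puncta in a synthetic cell and summarize morphology.

Builds a single-plane cell image with 12 round granules (0.084 um pixels,
snr 10), detects them with the robust background threshold and the >= 3x3 px
size rule, and prints counts, density per um^2 of cell area, and the
circular/amorphic classification.
"""

from granulekit import detect_granules, gen_granule_scene, summarize_cell

stack, cell_roi, truth = gen_granule_scene(n_granules=12, cell_diameter_um=10,
                                           snr=10, seed=3)
records = detect_granules(stack, cell_roi)
summary = summarize_cell("cell-1", records, cell_diameter_um=10.0)

print(f"true granules: {len(truth.truth['granules'])}, "
      f"detected: {summary.n_granules}")
print(f"cell area {summary.cell_area_um2:.2f} um^2 -> "
      f"{summary.granules_per_um2:.3f} granules/um^2")
for r in records[:3]:
    print(f"  granule {r.label}: area {r.area_um2:.3f} um^2, "
          f"circularity {r.circularity:.2f} -> {r.morphology}")
print("Circularity 4*pi*A/P^2 is ~1 for round granules; < 0.8 is amorphic, "
      "and a cell with any amorphic granule is an amorphic cell.")
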