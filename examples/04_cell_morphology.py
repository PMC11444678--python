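"""Rod-cell length and width from a binary mask.

Rasterizes a 6.0 × 0.7 µm spherocylinder at 160 nm pixels and measures it
back via the spur-pruned medial axis plus the capped-rod area relation.
"""

import myxospt as m

cell = m.make_cell(length_um=6.0, width_um=0.7, axis_angle=0.0,
                   center=(4.0, 2.0))
mask = cell.rasterize((26, 52), pixel_size_um=0.16)

rec = m.measure_morphology(mask, pixel_size_um=0.16)
print(f"true cell   : length 6.00 µm, width 0.70 µm")
print(f"measured    : length {rec.length_um:.2f} µm, width {rec.width_um:.2f} µm")
print(f"mask area   : {rec.area_px} px")
print()
print("Both dimensions come back within one pixel (0.16 µm); shape changes")
print("of this size distinguish wild-type rods from mutants with altered")
print("cell-wall synthesis.")
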