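# Background ROI template for the image-quality analysis.
#
# Twelve transaxial (x, y) positions in mm, placed on a 100-mm-radius
# circle at angles interleaved between the six sphere directions so that
# every ROI (up to 37 mm diameter) stays >= 15 mm from the phantom wall
# and from every sphere.  Each position is evaluated on the central
# sphere slice and on slices +/-10 mm and +/-20 mm (60 ROIs per sphere
# size in total), following the standard 12-position / 5-slice layout.
positions_mm:
  - [96.59, 25.88]
  - [70.71, 70.71]
  - [25.88, 96.59]
  - [-25.88, 96.59]
  - [-70.71, 70.71]
  - [-96.59, 25.88]
  - [-96.59, -25.88]
  - [-70.71, -70.71]
  - [-25.88, -96.59]
  - [25.88, -96.59]
  - [70.71, -70.71]
  - [96.59, -25.88]
slice_offsets_mm: [-20.0, -10.0, 0.0, 10.0, 20.0]
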