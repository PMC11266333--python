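# Default scanner: 34-sector ring, 4 axial modules of 4 transaxial blocks,
# 4 x 9 LYSO crystals per block (5.3 axial x 3.95 transaxial x 25 depth mm).
# ring_radius_mm is the crystal front-face radius; it is not a published
# value and was chosen so that the min-sector-difference-4 coincidence
# acceptance yields a ~70 cm transaxial FOV.  All lengths in mm.
n_sectors: 34
n_modules_axial: 4
n_blocks_per_module: 4
block_crystals_transaxial: 4
block_crystals_axial: 9
crystal_axial_mm: 5.3
crystal_transaxial_mm: 3.95
crystal_depth_mm: 25.0
ring_radius_mm: 372.0
crystal_gap_mm: 0.0
block_gap_mm: 0.0
module_gap_mm: 0.0
min_sector_difference: 4
lead_shielding: false
plastic_cover: false
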