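# Default chamber / 4T1 parameter set.
# Units are spelled out in each key name; see reecsim.config for the schema.

[geometry]
r_inner_um = 350.0
r_outer_um = 6000.0
height_um = 100.0
hole_diameter_um = 740.1

[species.oxygen]
D_um2_s = 3370.0
A_max_molecules_cell_s = 2.98e7
C_bulk_uM = 171.0   # concentration at the aperture (column-model corrected)
C_top_uM = 178.0    # fully oxygenated media at the top of the column

[species.glucose]
D_um2_s = 616.0
A_max_molecules_cell_s = 6.47e7
C_bulk_uM = 25000.0

[consumers]
areal_density_cells_cm2 = 2.0e5
height_um = 100.0

[column]
column_height_um = 250.0

[simulation]
t_end_s = 172800.0
inspection_interval_s = 60.0
rms_tol = 0.001
grid_spacing_um = 10.0
linear_consumption = false

[profiling]
bin_width_um = 50.0
smoothing_window = 5
front_fraction = 0.9
intensity_mode = "first_point"
distance_mode = "absolute"

[synth]
density_cells_cm2 = 2.0e5
response = "hypoxia_linear"
I_max = 1000.0
noise_sigma = 0.2
background = 0.0
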