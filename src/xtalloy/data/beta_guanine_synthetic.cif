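# SYNTHETIC approximation to the beta-guanine packing motif (Z=4,
# monoclinic, pi-stacking along a, H-bond chain along b, dimer links in the
# bc plane).  This is NOT the experimental crystal structure: cell metrics
# and the 5-atom toy molecule are idealized so that the contact topology,
# not the geometry, matches the real polymorph.  Generated by
# xtalloy.synthetic_data.make_toy_structure("beta4").
data_beta_guanine_synthetic
_cell_length_a    3.600000
_cell_length_b    6.000000
_cell_length_c    14.000000
_cell_angle_alpha 90.000000
_cell_angle_beta  96.000000
_cell_angle_gamma 90.000000
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
'x,y+1/2,z+1/4'
'x,y,z+1/2'
'x,y+1/2,z+3/4'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.250000 0.250000 0.125000
N2 N 0.250000 0.483333 0.125000
N3 N 0.250000 0.016667 0.125000
O4 O 0.290874 0.250000 0.225551
O5 O 0.209126 0.250000 0.024449
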