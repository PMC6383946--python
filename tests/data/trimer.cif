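data_TRIMER
#
_entry.id   TRIMER
#
_struct.entry_id   TRIMER
_struct.title   'Synthetic homotrimer test structure'
#
_cell.length_a   30.000
_cell.length_b   30.000
_cell.length_c   30.000
_cell.angle_alpha   90.00
_cell.angle_beta   90.00
_cell.angle_gamma   90.00
#
_symmetry.space_group_name_H-M   'P 1'
#
loop_
_entity.id
_entity.type
_entity.pdbx_description
1 polymer 'trimer subunit'
2 water water
#
loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_seq_one_letter_code
1 polypeptide(L) GAG
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . GLY A 1 1 ? 10.000 5.000 15.000 1.00 10.00 1 GLY A 1
ATOM 2 C CA . ALA A 1 2 ? 12.500 6.200 15.000 1.00 10.00 2 ALA A 1
ATOM 3 C CA . GLY A 1 3 ? 15.000 5.000 15.000 1.00 10.00 3 GLY A 1
ATOM 4 C CA . GLY B 1 1 ? 20.000 10.000 15.000 1.00 10.00 1 GLY B 1
ATOM 5 C CA . ALA B 1 2 ? 18.700 12.400 15.000 1.00 10.00 2 ALA B 1
ATOM 6 C CA . GLY B 1 3 ? 16.100 13.700 15.000 1.00 10.00 3 GLY B 1
ATOM 7 C CA . GLY C 1 1 ? 10.000 20.000 15.000 1.00 10.00 1 GLY C 1
ATOM 8 C CA . ALA C 1 2 ? 8.800 17.400 15.000 1.00 10.00 2 ALA C 1
ATOM 9 C CA . GLY C 1 3 ? 8.900 14.300 15.000 1.00 10.00 3 GLY C 1
HETATM 10 O O . HOH D 2 . ? 5.000 5.000 20.000 1.00 20.00 101 HOH A 1
HETATM 11 O O . HOH E 2 . ? 25.000 5.000 20.000 1.00 20.00 101 HOH B 1
HETATM 12 O O . HOH F 2 . ? 15.000 25.000 20.000 1.00 20.00 101 HOH C 1
#
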