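TITLE     SYNTHETIC PEPTIDE WITH LIGAND AND WATERS
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      6  CA  ALA A   2       3.984   2.834   0.000  1.00 10.00           C
ATOM      7  C   ALA A   2       5.503   2.696   0.000  1.00 10.00           C
ATOM      8  O   ALA A   2       6.062   1.601   0.000  1.00 10.00           O
ATOM      9  N   ALA A   3       6.189   3.838   0.000  1.00 10.00           N
ATOM     10  CA  ALA A   3       7.645   3.880   0.000  1.00 10.00           C
ATOM     11  C   ALA A   3       8.196   5.300   0.000  1.00 10.00           C
ATOM     12  O   ALA A   3       7.438   6.270   0.000  1.00 10.00           O
TER      13      ALA A   3
HETATM   14  C1  XYL A 101       4.000   6.000   3.000  1.00 15.00           C
HETATM   15  C2  XYL A 101       5.400   6.000   3.000  1.00 15.00           C
HETATM   16  O1  XYL A 101       6.100   7.200   3.000  1.00 15.00           O
HETATM   17  O   HOH A 201       0.000   5.000   5.000  1.00 25.00           O
HETATM   18  O   HOH A 202       9.000   0.000   5.000  1.00 25.00           O
END
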