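TITLE     TWO-MODEL SYNTHETIC DIPEPTIDE
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  5.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  5.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  5.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  5.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  5.00           N
ATOM      6  CA  ALA A   2       3.984   2.834   0.000  1.00  5.00           C
ATOM      7  C   ALA A   2       5.503   2.696   0.000  1.00  5.00           C
ATOM      8  O   ALA A   2       6.062   1.601   0.000  1.00  5.00           O
TER       9      ALA A   2
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.100   0.000   0.000  1.00  5.00           N
ATOM      2  CA  GLY A   1       1.558   0.000   0.000  1.00  5.00           C
ATOM      3  C   GLY A   1       2.109   1.420   0.000  1.00  5.00           C
ATOM      4  O   GLY A   1       1.351   2.390   0.000  1.00  5.00           O
ATOM      5  N   ALA A   2       3.432   1.536   0.000  1.00  5.00           N
ATOM      6  CA  ALA A   2       4.084   2.834   0.000  1.00  5.00           C
ATOM      7  C   ALA A   2       5.603   2.696   0.000  1.00  5.00           C
ATOM      8  O   ALA A   2       6.162   1.601   0.000  1.00  5.00           O
TER       9      ALA A   2
ENDMDL
END
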