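HEADER    DE NOVO PROTEIN                         01-JAN-00   XXXX
TITLE     HAND-WRITTEN THREE-RESIDUE FIXTURE (GLY-ALA-VAL)
SEQRES   1 A    3  GLY ALA VAL
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
TER       4      VAL A   3
END
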