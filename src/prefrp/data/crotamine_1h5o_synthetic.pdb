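HEADER    TOXIN                                   01-JAN-02   1H5O
TITLE     SYNTHETIC SEQUENCE-ONLY RENDITION OF CROTAMINE (PDB 1H5O)
REMARK    SEQRES-ONLY FIXTURE BUILT FROM THE PUBLISHED MATURE CROTAMINE
REMARK    SEQUENCE; NO COORDINATES. NOT THE DEPOSITED PDB FILE.
SEQRES   1 A   42  TYR LYS GLN CYS HIS LYS LYS GLY GLY HIS CYS PHE PRO
SEQRES   2 A   42  LYS GLU LYS ILE CYS LEU PRO PRO SER SER ASP PHE GLY
SEQRES   3 A   42  LYS MET ASP CYS ARG TRP ARG TRP LYS CYS CYS LYS LYS
SEQRES   4 A   42  GLY SER GLY
END
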