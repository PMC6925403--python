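H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
    3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
R PMID:6167991
A Hopp, T.P. and Woods, K.R.
T Prediction of protein antigenic determinants from amino acid sequences
J Proc. Natl. Acad. Sci. USA 78, 3824-3828 (1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.500   3.000   0.200   3.000  -1.000   0.200   3.000   0.000  -0.500  -1.800
   -1.800   3.000  -1.300  -2.500   0.000   0.300  -0.400  -3.400  -2.300  -1.500
//
H EISD840101
D Consensus normalized hydrophobicity scale (Eisenberg, 1984)
R PMID:6383201
A Eisenberg, D.
T Three-dimensional structure of membrane and surface proteins
J Ann. Rev. Biochem. 53, 595-623 (1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.620  -2.530  -0.780  -0.900   0.290  -0.850  -0.740   0.480  -0.400   1.380
    1.060  -1.500   0.640   1.190   0.120  -0.180  -0.050   0.810   0.260   1.080
//
H FAUJ830101
D Hydrophobic parameter pi (Fauchere-Pliska, 1983)
R
A Fauchere, J.L. and Pliska, V.
T Hydrophobic parameters pi of amino-acid side chains from the partitioning of
  N-acetyl-amino-acid amides
J Eur. J. Med. Chem. 18, 369-375 (1983)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.310  -1.010  -0.600  -0.770   1.540  -0.220  -0.640   0.000   0.130   1.800
    1.700  -0.990   1.230   1.790   0.720  -0.040   0.260   2.250   0.960   1.220
//
H BHAR880101
D Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)
R
A Bhaskaran, R. and Ponnuswamy, P.K.
T Positional flexibilities of amino acid residues in globular proteins
J Int. J. Peptide Protein Res. 32, 241-255 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.357   0.529   0.463   0.511   0.346   0.493   0.497   0.544   0.323   0.462
    0.365   0.466   0.295   0.314   0.509   0.507   0.444   0.305   0.420   0.386
//
H GRAR740102
D Polarity (Grantham, 1974)
R PMID:4843792
A Grantham, R.
T Amino acid difference formula to help explain protein evolution
J Science 185, 862-864 (1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    8.100  10.500  11.600  13.000   5.500  10.500  12.300   9.000  10.400   5.200
    4.900  11.300   5.700   5.200   8.000   9.200   8.600   5.400   6.200   5.900
//
H KARP850101
D Flexibility parameter for no rigid neighbors (Karplus-Schulz, 1985)
R
A Karplus, P.A. and Schulz, G.E.
T Prediction of chain flexibility in proteins
J Naturwissenschaften 72, 212-213 (1985)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.041   1.038   1.117   1.033   0.960   1.165   1.094   1.142   0.982   0.892
    0.967   1.093   0.947   0.930   1.055   1.169   1.073   0.925   0.961   0.982
//
H JANJ780101
D Average accessible surface area based transfer free energy (Janin, 1979)
R PMID:763335
A Janin, J.
T Surface and inside volumes in globular proteins
J Nature 277, 491-492 (1979)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.280  -1.140  -0.550  -0.520   0.970  -0.690  -1.010   0.430  -0.310   0.600
    0.600  -1.620   0.430   0.670  -0.420  -0.190  -0.050   0.290  -0.150   0.600
//
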