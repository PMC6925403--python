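residue	class	index	carbon_atoms	total_atoms
G	high	-2	2	7
A	high	-2	3	10
S	high	-2	3	11
P	high	-2	5	14
D	high	-2	4	13
T	moderate	-1	4	14
E	moderate	-1	5	16
N	moderate	-1	4	14
K	moderate	-1	6	21
C	moderate	-1	3	11
Q	moderate	-1	5	17
R	moderate	-1	6	23
V	moderate	-1	5	16
H	weak	2	6	17
L	weak	2	6	19
M	weak	2	5	17
I	weak	2	6	19
Y	weak	2	9	21
F	weak	2	9	20
W	weak	2	11	24
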