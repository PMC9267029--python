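# Element-keyed 12-6 Lennard-Jones parameters, Amber-family convention.
# R_i is Rmin/2 in Angstrom (pair minimum at R_i + R_j); epsilon in kcal/mol.
# Edit or replace via LJParameterTable.from_tsv for ligand-specific typing.
type_key	R_i	epsilon
H	1.4870	0.0157
C	1.9080	0.1094
N	1.8240	0.1700
O	1.6612	0.2100
S	2.0000	0.2500
P	2.1000	0.2000
F	1.7500	0.0610
CL	1.9480	0.2650
BR	2.2200	0.3200
I	2.3500	0.4000
MG	0.7926	0.8947
NA	1.8680	0.00277
K	2.6580	0.000328
CA	1.7131	0.4598
ZN	1.1000	0.0125
FE	1.2000	0.0500
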