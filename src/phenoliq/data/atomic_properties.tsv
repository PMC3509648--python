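# Atomic properties used as descriptor weights, one row per element.
# mass: atomic mass (amu); vdw_volume: van der Waals volume (A^3);
# sanderson_en: Sanderson electronegativity (dimensionless);
# polarizability: atomic polarizability (A^3).
# Values follow the standard carbon-referenced weighting convention used by
# molecular-descriptor software; weights are divided by the carbon value at
# load time so that weight(C) = 1 for every scheme.
element	mass	vdw_volume	sanderson_en	polarizability
H	1.01	6.709	2.592	0.667
C	12.01	22.449	2.746	1.760
N	14.01	15.599	3.194	1.100
O	16.00	11.494	3.654	0.802
S	32.07	24.429	2.957	2.900
P	30.97	24.429	2.515	3.630
F	19.00	9.203	4.000	0.557
Cl	35.45	23.228	3.475	2.180
Br	79.90	31.059	3.219	3.050
I	126.90	38.792	2.778	5.350
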