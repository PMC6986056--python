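# Textbook Hammett sigma-para and Hansch-Fujita pi constants for classic
# benzene substituents (standard literature compilation values).
smiles	sigma_para_exp	pi_exp
[*][H]	0.00	0.00
[*]C	-0.17	0.56
[*]CC	-0.15	1.02
[*]C(C)C	-0.15	1.53
[*]C(C)(C)C	-0.20	1.98
[*]F	0.06	0.14
[*]Cl	0.23	0.71
[*]Br	0.23	0.86
[*]I	0.18	1.12
[*]C(F)(F)F	0.54	0.88
[*]C#N	0.66	-0.57
[*][N+](=O)[O-]	0.78	-0.28
[*]O	-0.37	-0.67
[*]OC	-0.27	-0.02
[*]N	-0.66	-1.23
[*]NC	-0.70	-0.47
[*]N(C)C	-0.83	0.18
[*]C(C)=O	0.50	-0.55
[*]C(=O)OC	0.45	-0.01
[*]C(N)=O	0.36	-1.49
[*]C=O	0.42	-0.65
[*]SC	0.00	0.61
[*]S(C)(=O)=O	0.72	-1.63
[*]OC(F)(F)F	0.35	1.04
[*]c1ccccc1	-0.01	1.96
[*]C=C	-0.02	0.82
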