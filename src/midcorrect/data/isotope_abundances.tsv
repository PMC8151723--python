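# Natural isotope abundances (mole fraction) by nominal mass shift above the
# lightest principal isotope. Representative isotopic compositions from the
# IUPAC/CIAAW compilation (Berglund & Wieser, Pure Appl. Chem. 83:397, 2011),
# as also tabulated in the CRC Handbook. Pinned here so results are bit-stable
# regardless of upstream table revisions.
# element	mass_shift	abundance
C	0	0.9893
C	1	0.0107
H	0	0.999885
H	1	0.000115
N	0	0.99636
N	1	0.00364
O	0	0.99757
O	1	0.00038
O	2	0.00205
S	0	0.9499
S	1	0.0075
S	2	0.0425
S	4	0.0001
Si	0	0.92223
Si	1	0.04685
Si	2	0.03092
P	0	1.0
Na	0	1.0
Cl	0	0.7576
Cl	2	0.2424
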