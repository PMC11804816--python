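# Chlorpromazine heavy-atom skeleton (21 atoms, 23 bonds).
# Vertex ids follow the SMILES atom order of
#   CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
# 1 C, 2 N, 3 C, 4 C, 5 C, 6 C, 7 N, 8-13 ring C, 14 S,
# 15-18 C, 19 Cl, 20-21 ring C.
1 2
2 3
2 4
4 5
5 6
6 7
7 8
7 21
8 9
8 13
9 10
10 11
11 12
12 13
13 14
14 15
15 16
15 21
16 17
17 18
18 19
18 20
20 21
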