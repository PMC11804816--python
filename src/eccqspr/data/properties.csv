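id,BP,MP,E,FP,MR,C,MW,R
a,450.1,60,70.9,226.0,92.83,339,355.33,93.76
b,506.0,242,77.6,259.8,108.2,510,480.4,110.98
c,515.6,65,73.8,265.7,112.8,432,370.6,113.52
d,599.0,114,89.2,316.1,126.5,711,443.62,137.85
e,529.0,151.5,84.6,273.8,101.0,451,375.9,102.59
f,489.2,183,75.5,249.6,93.7,446,326.8,97.36
g,554.8,213,83.6,289.3,114.1,573,412.936,116.72
h,458.6,109,71.9,231.1,92.1,450,327.81,95.11
i,556.5,172,88.2,290.4,110.2,496,383.51,114.09
j,646.2,139.0,95.3,344.6,120.3,559,448.4,124.34
k,572.4,170.0,85.8,300.0,111.7,731,410.5,111.7
l,476,195,74.0,241.7,92.2,432,312.432,107.17
m,592.1,95,88.3,311.9,120.7,623,440.941,131.77
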