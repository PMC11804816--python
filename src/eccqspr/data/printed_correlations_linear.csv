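index,BP,MP,E,FP,MR,C,MW,R
zeta,0.0539,0.1010,0.3025,0.2232,0.1857,0.4332,0.1449,0.1549
avec,0.2119,0.1169,0.2375,0.1334,0.0520,0.3121,0.0316,0.01
m1_star,0.0346,0.1044,0.2818,0.2191,0.1766,0.4602,0.1382,0.1480
m1_dstar,0.0927,0.0741,0.3210,0.2676,0.2789,0.5134,0.2433,0.2528
m2_star,0.0985,0.1136,0.2702,0.1844,0.1054,0.3882,0.0640,0.0678
ga4,0.2449,0.0837,0.3397,0.3558,0.41,0.6602,0.3547,0.4094
abc,0.3758,0.0906,0.1122,0.0141,0.1020,0.1500,0.0843,0.1533
he,0.5010,0.0849,0.0436,0.1091,0.2400,0.0141,0.2081,0.2997
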