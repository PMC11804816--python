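index,BP,MP,E,FP,MR,C,MW,R
zeta,0.2804,0.1044,0.3625,0.2636,0.1857,0.4343,0.1975,0.1552
avec,0.1554,0.1353,0.2831,0.14,0.1701,0.3884,0.2755,0.1962
m1_star,0.3158,0.1311,0.3110,0.2518,0.1797,0.4671,0.1944,0.1503
m1_dstar,0.4426,0.0954,0.42,0.3748,0.3164,0.5311,0.2451,0.3169
m2_star,0.2653,0.1183,0.3140,0.2140,0.1192,0.3934,0.1985,0.11
ga4,0.3682,0.3855,0.3403,0.3603,0.4145,0.6831,0.3633,0.4358
abc,0.4887,0.2355,0.2586,0.0994,0.1835,0.3175,0.2670,0.2608
he,0.5882,0.2205,0.3351,0.2383,0.2439,0.2421,0.2247,0.2998
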