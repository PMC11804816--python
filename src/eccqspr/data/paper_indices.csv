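id,zeta,avec,m1_star,m1_dstar,m2_star,ga4,abc,he
a,156,7.4286,332,5978,1221,22.9450,1.6352,3.2715
b,294,10.5,638,15718,3345,30.9631,1.3187,3.0846
c,218,8.75,478,10238,2074,27.9487,1.5535,3.3510
d,331,11.0333,711,17531,3908,32.9617,1.3154,3.1387
e,339,13.0384,721,14509,4773,27.9782,0.8724,2.2449
f,352,12.5714,799,16738,5139,31.9730,1.0501,2.6557
g,179,7.782,393,7135,1516,25.9401,1.7326,3.5329
h,315,11.6666,691,15261,4099,29.9731,1.1065,2.6988
i,430,14.3333,875,23086,6340,30.9785,0.8447,2.2666
j,180,7.8261,397,6906,1548,25.9413,1.7099,3.4999
k,395,13.1667,887,22057,5946,33.9761,1.0407,2.6923
l,170,7.7272,377,6406,1450,24.9444,1.6689,3.4020
m,383,12.3548,849,22057,5259,34.9685,1.1956,2.9876
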