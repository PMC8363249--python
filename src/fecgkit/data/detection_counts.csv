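dataset,record,channels,filter_order,N,N_std,imfs,n,TP,FP,FN,acc,se,ppv,f1
fecgdarha,r01,1+3+4,2,10,0.5,4+7,644,644,0,0,100,100,100,100
fecgdarha,r02,1+4,16,10,0.4,3+4,660,660,0,0,100,100,100,100
fecgdarha,r03,2+4,86,60,0.4,2+3+4+7,684,679,1,5,99.12,99.27,99.85,99.56
fecgdarha,r04,2+3,46,30,0.8,2+3+5,632,577,26,55,87.69,91.30,95.69,93.44
fecgdarha,r05,1+4,16,10,0.5,3+4,645,645,0,0,100,100,100,100
fecgdarha,r06,1+2+3+4,98,30,0.9,2+4+7,674,648,22,26,93.10,96.14,96.72,96.43
fecgdarha,r07,1+3+4,46,60,0.6,2+5,627,591,17,36,91.77,94.26,97.20,95.71
fecgdarha,r08,1+4,30,60,0.4,4+5,651,650,0,1,99.85,99.85,100,99.92
fecgdarha,r09,1+4,16,10,0.4,2+3+4,657,656,0,1,99.85,99.85,100,99.92
fecgdarha,r10,1+2+3+4,52,30,0.9,5+8,637,630,26,7,95.02,98.90,96.04,97.45
fecgdarha,r11,1+2+3+4,80,60,0.2,3+7,705,460,169,245,52.63,65.25,73.13,68.97
fecgdarha,r12,1+2+3+4,100,60,0.9,2+4+8,685,659,16,26,94.01,96.20,97.63,96.91
challenge2013,a01,1+2+3,10,30,0.5,2+4+5+6+7,145,137,3,8,92.57,94.48,97.86,94.14
challenge2013,a02,1+2+4,2,30,0.5,4+5+8,160,81,39,79,40.70,50.63,67.50,57.86
challenge2013,a03,1+4,100,10,0.1,4+6+8,128,127,1,1,98.45,99.22,99.22,99.22
challenge2013,a04,1+2,64,10,0.1,3+5+6,129,129,0,0,100,100,100,100
challenge2013,a05,1+3,32,10,0.1,3+4,129,129,0,0,100,100,100,100
challenge2013,a06,2+4,24,30,0.8,2+4+8,160,106,24,54,57.61,66.25,81.54,73.10
challenge2013,a07,1+2+3+4,66,10,0.3,2+3+6,130,70,48,60,39.33,53.85,59.32,56.45
challenge2013,a08,1+4,100,10,0.1,3,128,128,0,0,100,100,100,100
challenge2013,a09,1+4,94,30,0.1,6+10,130,40,50,90,22.22,30.77,44.44,36.36
challenge2013,a10,2+4,98,60,0.5,3,175,149,5,26,82.78,85.14,96.75,90.58
challenge2013,a11,1+4,24,60,0.6,4+5+6+9,140,77,24,63,46.95,55,76.24,63.90
challenge2013,a12,1+3+4,14,10,0.1,2+3+4,138,136,2,2,97.14,98.55,98.55,98.55
challenge2013,a13,2+4,36,60,0.7,2+3+5,126,124,1,2,97.64,98.41,99.20,98.81
challenge2013,a14,1+2+3+4,10,10,0.2,4+6+9,123,120,2,3,96,97.56,98.36,97.96
challenge2013,a15,1+4,94,10,0.1,3+4,134,134,0,0,100,100,100,100
challenge2013,a16,1+4,40,10,0.7,5,130,55,54,75,29.89,42.31,50.46,46.03
challenge2013,a17,1+4,100,10,0.1,3+4,132,132,0,0,100,100,100,100
challenge2013,a18,1+2+3+4,34,30,0.9,3+5+6+7,150,29,80,121,12.61,19.33,26.61,22.39
challenge2013,a19,3+4,42,10,0.9,5,127,126,1,1,98.44,99.21,99.21,99.21
challenge2013,a20,1+4,96,60,0.9,5,131,117,6,14,85.40,89.31,95.12,92.13
challenge2013,a21,2+3+4,4,60,0.7,3+6+7,145,102,11,43,65.39,70.35,90.27,79.07
challenge2013,a22,1+4,32,10,0.1,4,126,126,0,0,100,100,100,100
challenge2013,a23,1+3,36,60,0.8,5+9,126,124,1,2,97.64,98.41,99.20,98.81
challenge2013,a24,1+3,50,30,0.6,2+4+5,123,118,1,5,95.16,95.94,99.16,97.52
challenge2013,a25,2+3,94,30,0.8,2+3+5,125,125,0,0,100,100,100,100
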