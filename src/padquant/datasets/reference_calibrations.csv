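analyte,method_id,label,slope,slope_se,sens_error_pct_printed,lod_printed,conc_unit
BTB,1,R,-0.594,0.018,3.03,22.07,mg/L
BTB,2,G,-0.386,0.012,3.11,16.54,mg/L
BTB,3,B,-0.212,0.016,7.55,40.13,mg/L
BTB,4,(R+G+B)/3,-0.411,0.009,2.19,13.62,mg/L
BTB,5,log(R0/R),0.00164,0.00002,1.22,11.84,mg/L
BTB,6,log(G0/G),0.00087,0.00004,4.60,24.66,mg/L
BTB,7,log(B0/B),0.00043,0.00004,9.30,66.06,mg/L
BTB,8,R0-R,0.593,0.017,2.87,22.07,mg/L
BTB,9,G0-G,0.386,0.012,3.11,16.54,mg/L
BTB,10,B0-B,0.213,0.015,7.04,55.14,mg/L
BTB,11,dR+dG+dB,1.238,0.015,1.21,10.33,mg/L
BTB,12,(R+G+B)/R,0.00535,0.00007,1.31,6.79,mg/L
BTB,13,(R+G+B)/G,-0.00044,0.00005,11.36,92.59,mg/L
BTB,14,(R+G+B)/B,-0.00268,0.00016,5.97,46.79,mg/L
BTB,15,R/G,-0.00139,0.00006,4.32,27.59,mg/L
BTB,16,G/B,-0.00072,0.00005,6.94,73.65,mg/L
BTB,17,R/B,-0.00196,0.00008,4.08,40.45,mg/L
BTB,18,ED,0.740,0.007,0.95,9.49,mg/L
BTB,19,-log(RGB/R0G0B0),0.00294,0.00008,2.72,23.13,mg/L
Zn,1,R,,,,,mmol/L
Zn,2,G,-78.65,1.27,1.61,0.12,mmol/L
Zn,3,B,,,,,mmol/L
Zn,4,(R+G+B)/3,-32.20,1.58,4.91,0.15,mmol/L
Zn,5,log(R0/R),,,,,mmol/L
Zn,6,log(G0/G),0.241,0.007,2.90,0.12,mmol/L
Zn,7,log(B0/B),,,,,mmol/L
Zn,8,R0-R,,,,,mmol/L
Zn,9,G0-G,78.75,0.99,1.26,0.12,mmol/L
Zn,10,B0-B,,,,,mmol/L
Zn,11,dR+dG+dB,82.14,4.24,5.16,0.16,mmol/L
Zn,12,(R+G+B)/R,-0.341,0.031,9.09,0.25,mmol/L
Zn,13,(R+G+B)/G,1.172,0.106,9.01,0.21,mmol/L
Zn,14,(R+G+B)/B,,,,,mmol/L
Zn,15,R/G,0.747,0.059,7.90,0.13,mmol/L
Zn,16,G/B,-0.903,0.077,8.53,0.22,mmol/L
Zn,17,R/B,,,,,mmol/L
Zn,18,ED,77.482,0.689,0.89,0.09,mmol/L
Zn,19,-log(RGB/R0G0B0),0.243,0.016,6.58,0.17,mmol/L
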