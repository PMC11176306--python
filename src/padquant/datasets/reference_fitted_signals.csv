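analyte,method_id,label,c_low,c_high,conc_unit,s_low,u_low,s_high,u_high,ratio_printed
BTB,1,R,60,65,mg/L,186.07,3.41,183.10,3.27,0.89
BTB,2,G,60,65,mg/L,206.16,1.62,204.23,1.56,1.21
BTB,3,B,60,65,mg/L,216.87,1.54,215.87,1.69,0.62
BTB,4,(R+G+B)/3,60,65,mg/L,202.77,1.19,200.71,1.16,1.75
BTB,5,log(R0/R),60,65,mg/L,0.097,0.004,0.105,0.004,2.00
BTB,6,log(G0/G),60,65,mg/L,0.041,0.005,0.046,0.005,1.00
BTB,7,log(B0/B),60,65,mg/L,0.020,0.003,0.022,0.004,0.57
BTB,8,R0-R,60,65,mg/L,43.96,3.39,46.93,3.25,0.89
BTB,9,G0-G,60,65,mg/L,19.89,1.62,21.82,1.57,1.21
BTB,10,B0-B,60,65,mg/L,10.00,1.41,11.07,1.55,0.72
BTB,11,dR+dG+dB,60,65,mg/L,73.98,2.19,80.17,2.12,2.87
BTB,12,(R+G+B)/R,60,65,mg/L,3.307,0.006,3.333,0.006,4.33
BTB,13,(R+G+B)/G,60,65,mg/L,2.942,0.006,2.939,0.006,0.50
BTB,14,(R+G+B)/B,60,65,mg/L,2.797,0.014,2.784,0.013,0.96
BTB,15,R/G,60,65,mg/L,0.892,0.003,0.885,0.003,2.33
BTB,16,G/B,60,65,mg/L,0.948,0.007,0.945,0.006,0.46
BTB,17,R/B,60,65,mg/L,0.849,0.009,0.839,0.009,1.11
BTB,18,ED,60,65,mg/L,50.54,1.09,54.24,1.09,3.39
BTB,19,-log(RGB/R0G0B0),60,65,mg/L,0.16,0.01,0.18,0.01,2.00
Zn,2,G,0.30,0.35,mmol/L,169.63,2.14,165.70,1.99,1.90
Zn,4,(R+G+B)/3,0.30,0.35,mmol/L,165.00,1.41,163.39,1.31,1.18
Zn,6,log(G0/G),0.30,0.35,mmol/L,0.063,0.01,0.075,0.01,1.20
Zn,9,G0-G,0.30,0.35,mmol/L,25.84,1.70,29.77,1.57,2.40
Zn,11,dR+dG+dB,0.30,0.35,mmol/L,29.02,4.4,33.13,4.19,0.96
Zn,12,(R+G+B)/R,0.30,0.35,mmol/L,2.13,0.03,2.11,0.02,0.80
Zn,13,(R+G+B)/G,0.30,0.35,mmol/L,2.95,0.09,3.01,0.09,0.67
Zn,15,R/G,0.30,0.35,mmol/L,1.40,0.03,1.43,0.02,1.20
Zn,16,G/B,0.30,0.35,mmol/L,1.87,0.09,1.83,0.09,0.44
Zn,18,ED,0.30,0.35,mmol/L,26.91,0.94,30.79,0.88,4.26
Zn,19,-log(RGB/R0G0B0),0.30,0.35,mmol/L,0.079,0.015,0.091,0.015,0.80
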