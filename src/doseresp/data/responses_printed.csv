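dosemeter_type,geometry,zenith_angle_deg,mean_energy_keV,mean_B,K
EPD,AP,,119,1.38,1.010
EPD,AP,,207,1.35,1.008
EPD,AP,,662,1.20,1.000
EPD,ROT,30,119,0.84,1.021
EPD,ROT,30,207,0.99,1.008
EPD,ROT,30,662,0.87,1.031
EPD,ROT,60,119,0.83,1.021
EPD,ROT,60,207,0.97,1.027
EPD,ROT,60,662,0.86,1.008
EPD,ROT,90,119,0.83,1.011
EPD,ROT,90,207,0.97,1.015
EPD,ROT,90,662,0.87,1.014
EPD,ROT,120,119,0.78,1.018
EPD,ROT,120,207,0.92,1.029
EPD,ROT,120,662,0.83,1.015
EPD,ROT,150,119,0.51,1.039
EPD,ROT,150,207,0.69,1.041
EPD,ROT,150,662,0.64,1.022
EPD,ISO,,119,0.77,1.009
EPD,ISO,,207,0.92,1.011
EPD,ISO,,662,0.82,1.008
GB,AP,,119,1.47,1.046
GB,AP,,207,1.30,1.035
GB,AP,,662,1.21,1.021
GB,ROT,30,119,0.65,1.056
GB,ROT,30,207,0.84,1.059
GB,ROT,30,662,0.87,1.072
GB,ROT,60,119,0.80,1.014
GB,ROT,60,207,0.89,1.037
GB,ROT,60,662,0.87,1.036
GB,ROT,90,119,0.83,1.040
GB,ROT,90,207,0.92,1.017
GB,ROT,90,662,0.88,1.015
GB,ROT,120,119,0.82,1.059
GB,ROT,120,207,0.90,1.021
GB,ROT,120,662,0.89,1.009
GB,ROT,150,119,0.80,1.058
GB,ROT,150,207,0.79,1.023
GB,ROT,150,662,0.79,1.020
GB,ISO,,119,0.79,1.020
GB,ISO,,207,0.88,1.014
GB,ISO,,662,0.86,1.014
LB,AP,,119,1.98,1.049
LB,AP,,207,1.55,1.062
LB,AP,,662,1.19,1.079
LB,ROT,30,119,1.15,1.055
LB,ROT,30,207,1.01,1.065
LB,ROT,30,662,0.90,1.097
LB,ROT,60,119,1.14,1.127
LB,ROT,60,207,1.03,1.064
LB,ROT,60,662,0.88,1.066
LB,ROT,90,119,1.17,1.046
LB,ROT,90,207,1.08,1.017
LB,ROT,90,662,0.96,1.060
LB,ROT,120,119,1.16,1.042
LB,ROT,120,207,1.07,1.083
LB,ROT,120,662,0.87,1.034
LB,ROT,150,119,1.09,1.128
LB,ROT,150,207,0.90,1.021
LB,ROT,150,662,0.80,1.094
LB,ISO,,119,1.14,1.037
LB,ISO,,207,1.03,1.025
LB,ISO,,662,0.89,1.029
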