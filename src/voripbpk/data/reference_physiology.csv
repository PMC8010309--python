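age_yr,sex,weight_kg,height_cm,v_lung,v_brain,v_heart,v_kidney,v_liver,v_spleen,v_gut_wall,v_stomach,v_pancreas,v_muscle,v_adipose,v_skin,v_bone,v_gonads,v_venous_blood,v_arterial_blood,q_brain,q_heart,q_kidney,q_liver,q_gut_wall,q_stomach,q_pancreas,q_spleen,q_muscle,q_adipose,q_skin,q_bone,q_gonads,q_lung,co_l_h,gfr_ml_min,hematocrit,si_surface_cm2,si_lumen_l
0.25,male,6.0,61,0.07,0.6,0.03,0.045,0.2,0.015,0.15,0.03,0.01,1.2,1.41304,0.25,0.69231,0.001,0.3456,0.1344,15.2456,2.4393,9.1474,3.9639,7.9277,0.6098,0.6098,1.8295,4.2688,1.8295,3.0491,3.0491,0.0305,54.0,54.0,20,0.35,1114.0,0.0844
1.0,male,10.0,76,0.08,0.95,0.05,0.07,0.33,0.029,0.22,0.05,0.02,1.9,2.5,0.35,1.30769,0.0015,0.576,0.224,27.2285,3.8898,15.5592,6.3209,12.6418,0.9724,0.9724,2.9173,6.8071,2.9173,4.8622,4.8622,0.0486,90.0,90.0,45,0.36,1605.0,0.1216
5.0,male,19.0,109,0.125,1.245,0.085,0.11,0.57,0.05,0.37,0.085,0.035,5.6,3.80435,0.9,2.53846,0.002,1.08,0.42,51.1416,6.8189,32.3896,11.0807,22.1613,1.7047,1.7047,5.1142,13.6377,5.1142,8.5236,8.5236,0.0852,168.0,168.0,65,0.37,2650.0,0.2007
10.0,male,32.0,138,0.21,1.31,0.14,0.18,0.83,0.08,0.55,0.12,0.06,11.0,6.52174,1.5,4.15385,0.004,1.8,0.7,60.5904,9.6945,46.0487,15.7535,31.507,2.4236,2.4236,7.2708,24.2361,9.6945,12.1181,12.1181,0.1212,234.0,234.0,90,0.39,3869.0,0.2931
15.0,male,56.0,167,0.33,1.42,0.23,0.25,1.3,0.13,0.83,0.14,0.11,24.0,9.23913,2.5,6.61538,0.025,3.168,1.232,54.0688,14.4184,68.4872,23.4298,46.8596,3.6046,3.6046,10.8138,50.4642,18.0229,18.0229,18.0229,0.1802,330.0,330.0,110,0.42,5631.0,0.4266
18.0,male,73.0,176,0.5,1.45,0.33,0.31,1.8,0.15,1.02,0.15,0.14,29.0,15.86957,3.3,8.07692,0.035,4.032,1.568,51.1196,17.0399,80.9394,27.6898,55.3796,4.26,4.26,12.7799,72.4194,21.2998,21.2998,21.2998,0.213,390.0,390.0,115,0.44,6600.0,0.5
30.0,male,73.0,176,0.5,1.45,0.33,0.31,1.8,0.15,1.02,0.15,0.14,29.0,15.86957,3.3,8.07692,0.035,4.032,1.568,51.1196,17.0399,80.9394,27.6898,55.3796,4.26,4.26,12.7799,72.4194,21.2998,21.2998,21.2998,0.213,390.0,390.0,115,0.44,6600.0,0.5
80.0,male,73.0,176,0.5,1.45,0.33,0.31,1.8,0.15,1.02,0.15,0.14,29.0,15.86957,3.3,8.07692,0.035,4.032,1.568,51.1196,17.0399,80.9394,27.6898,55.3796,4.26,4.26,12.7799,72.4194,21.2998,21.2998,21.2998,0.213,390.0,390.0,115,0.44,6600.0,0.5
0.25,female,5.6,60,0.068,0.58,0.028,0.043,0.19,0.014,0.145,0.028,0.01,1.1,1.41304,0.24,0.65385,0.0005,0.324,0.126,14.3986,2.3038,8.6392,3.7436,7.4873,0.5759,0.5759,1.7278,4.0316,1.7278,2.8797,2.8797,0.0288,51.0,51.0,19,0.35,1067.0,0.0809
1.0,female,9.5,74,0.076,0.9,0.046,0.065,0.32,0.027,0.21,0.047,0.019,1.8,2.6087,0.33,1.23077,0.0008,0.5472,0.2128,25.4133,3.6305,14.5219,5.8995,11.799,0.9076,0.9076,2.7229,6.3533,2.7229,4.5381,4.5381,0.0454,84.0,84.0,43,0.36,1544.0,0.117
5.0,female,18.0,108,0.12,1.18,0.08,0.105,0.55,0.048,0.355,0.082,0.034,5.3,4.13043,0.85,2.38462,0.002,1.008,0.392,49.3151,6.5753,31.2329,10.6849,21.3699,1.6438,1.6438,4.9315,13.1507,4.9315,8.2192,8.2192,0.0822,162.0,162.0,62,0.37,2567.0,0.1945
10.0,female,31.0,137,0.2,1.26,0.13,0.17,0.81,0.08,0.53,0.115,0.058,10.5,7.6087,1.4,3.92308,0.004,1.728,0.672,57.4832,9.1973,43.6872,14.9456,29.8912,2.2993,2.2993,6.898,22.9933,9.1973,11.4966,11.4966,0.115,222.0,222.0,85,0.39,3795.0,0.2875
15.0,female,53.0,161,0.3,1.3,0.22,0.24,1.3,0.13,0.8,0.13,0.1,17.0,15.21739,2.0,5.53846,0.01,2.808,1.092,49.1535,13.1076,62.2611,21.2998,42.5997,3.2769,3.2769,9.8307,45.8766,16.3845,16.3845,16.3845,0.1638,300.0,300.0,100,0.4,5379.0,0.4075
18.0,female,60.0,163,0.42,1.3,0.25,0.275,1.4,0.13,0.92,0.14,0.12,17.5,19.56522,2.3,6.0,0.011,2.952,1.148,46.4009,15.467,73.4681,25.1338,50.2676,3.8667,3.8667,11.6002,65.7346,19.3337,19.3337,19.3337,0.1933,354.0,354.0,100,0.4,5758.0,0.4362
30.0,female,60.0,163,0.42,1.3,0.25,0.275,1.4,0.13,0.92,0.14,0.12,17.5,19.56522,2.3,6.0,0.011,2.952,1.148,46.4009,15.467,73.4681,25.1338,50.2676,3.8667,3.8667,11.6002,65.7346,19.3337,19.3337,19.3337,0.1933,354.0,354.0,100,0.4,5758.0,0.4362
80.0,female,60.0,163,0.42,1.3,0.25,0.275,1.4,0.13,0.92,0.14,0.12,17.5,19.56522,2.3,6.0,0.011,2.952,1.148,46.4009,15.467,73.4681,25.1338,50.2676,3.8667,3.8667,11.6002,65.7346,19.3337,19.3337,19.3337,0.1933,354.0,354.0,100,0.4,5758.0,0.4362
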