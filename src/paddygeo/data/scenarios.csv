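dataset_code,nutrient,dose,event,mean,variance,cv,minimum,maximum,skewness,kurtosis,family,c0,c1,ratio,range_a,r2,me,nmse
NH4-10,NH4-N,0,1,20.07,14.67,19.1,11.16,28.80,-0.047,-0.405,spherical,1.09,14.20,7.1,47.0,0.923,0.003,1.004
NH4-11,NH4-N,625,1,28.87,17.09,14.3,20.42,39.72,0.159,-0.435,spherical,6.37,10.41,38.0,45.1,0.663,-0.011,0.994
NH4-12,NH4-N,1250,1,27.30,30.56,20.3,11.62,43.63,0.064,0.856,spherical,13.58,19.05,41.6,68.9,0.932,-0.016,0.926
NH4-20,NH4-N,0,2,24.73,15.29,15.8,17.09,35.28,0.319,-0.530,spherical,0.00,15.57,0.0,40.9,0.876,-0.003,1.147
NH4-21,NH4-N,625,2,27.36,11.21,12.2,21.43,37.38,0.654,-0.036,exponential,0.00,12.25,0.0,59.5,0.912,-0.005,0.992
NH4-22,NH4-N,1250,2,28.50,12.56,12.4,19.79,36.94,0.099,-0.775,exponential,0.00,13.08,0.0,49.8,0.869,-0.019,1.000
NH4-30,NH4-N,0,3,37.74,24.14,13.0,28.84,48.52,0.433,-0.820,spherical,1.95,24.15,7.5,53.2,0.639,-0.001,0.813
NH4-31,NH4-N,625,3,43.92,31.23,12.7,30.38,55.38,-0.462,-0.251,spherical,0.00,33.96,0.0,71.9,0.907,0.002,0.922
NH4-32,NH4-N,1250,3,38.84,14.25,9.7,29.60,48.54,0.126,-0.033,spherical,2.60,13.92,15.7,84.6,0.972,-0.008,0.937
P-10,Olsen-P,0,1,5.52,1.75,24.0,2.50,8.04,0.041,-0.730,spherical,0.23,1.59,12.6,51.7,0.835,-0.052,1.060
P-11,Olsen-P,625,1,6.72,2.03,21.2,3.74,10.72,0.450,-0.346,spherical,0.61,1.54,28.4,64.0,0.836,-0.003,1.020
P-12,Olsen-P,1250,1,8.57,2.60,18.8,5.04,12.33,-0.160,-0.274,spherical,0.44,2.29,16.1,53.0,0.850,0.002,0.903
P-20,Olsen-P,0,2,10.36,4.75,21.0,6.61,18.45,1.069,1.562,spherical,0.42,4.86,8.0,65.2,0.951,-0.000,1.097
P-21,Olsen-P,625,2,13.12,6.50,19.4,7.30,18.43,0.012,-0.670,spherical,0.43,6.24,6.4,47.7,0.944,-0.019,0.996
P-22,Olsen-P,1250,2,11.93,3.39,15.4,8.72,17.34,0.502,0.037,spherical,1.53,1.97,43.7,76.3,0.908,-0.014,1.029
P-30,Olsen-P,0,3,7.14,3.39,25.8,3.50,14.26,0.894,1.633,spherical,1.41,2.30,38.0,73.9,0.976,0.002,0.848
P-31,Olsen-P,625,3,8.67,2.72,19.1,4.79,13.17,0.194,-0.319,spherical,0.74,2.11,26.0,57.7,0.843,0.027,0.855
P-32,Olsen-P,1250,3,7.45,3.02,23.3,4.05,10.69,0.111,-0.883,spherical,0.89,2.25,28.3,60.0,0.912,0.001,0.941
K-10,Mehlich-K,0,1,38.15,47.95,18.2,26.56,64.64,1.012,1.551,spherical,4.97,46.74,9.6,59.7,0.861,0.011,1.184
K-11,Mehlich-K,625,1,44.41,36.93,13.7,34.26,65.21,0.822,0.897,spherical,6.55,33.12,16.5,54.2,0.903,-0.005,0.948
K-12,Mehlich-K,1250,1,50.41,35.78,11.9,38.24,70.53,0.380,0.387,spherical,15.96,21.35,42.8,51.4,0.925,0.013,0.901
K-20,Mehlich-K,0,2,32.09,23.54,15.1,22.01,42.35,0.004,-0.969,spherical,6.73,18.65,26.5,65.5,0.891,0.006,0.954
K-21,Mehlich-K,625,2,36.46,86.97,25.6,19.86,59.87,0.277,-0.860,spherical,14.61,75.20,16.3,52.3,0.887,0.049,0.863
K-22,Mehlich-K,1250,2,40.44,57.47,18.8,28.73,59.68,0.355,-0.649,spherical,16.56,43.79,27.4,58.9,0.783,0.004,0.782
K-30,Mehlich-K,0,3,19.41,7.48,14.1,12.43,25.30,0.019,-0.647,spherical,1.46,6.66,18.0,63.1,0.899,-0.024,0.882
K-31,Mehlich-K,625,3,18.01,5.78,13.4,12.42,23.95,0.137,-0.022,spherical,2.46,3.71,39.9,68.2,0.921,0.003,1.075
K-32,Mehlich-K,1250,3,17.25,9.56,17.9,11.34,23.23,0.177,-1.038,spherical,3.52,6.84,34.0,76.8,0.960,-0.008,0.690
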