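arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,eosinophil,pre,0,24,1.00,0.13
reference,eosinophil,4h,5,3,2.21,0.23
reference,eosinophil,4h,7.5,3,0.67,0.11
reference,eosinophil,4h,7.7,3,0.53,0.13
reference,eosinophil,4h,10,3,0.36,0.12
reference,eosinophil,4h,15,3,0.38,0.01
reference,eosinophil,4h,20,3,0.45,0.03
reference,eosinophil,d1,5,3,0.48,0.09
reference,eosinophil,d1,7.5,3,0.83,0.32
reference,eosinophil,d1,7.7,3,0.60,0.18
reference,eosinophil,d1,10,3,0.70,0.23
reference,eosinophil,d1,15,3,0.59,0.17
reference,eosinophil,d1,20,3,0.47,0.13
reference,eosinophil,d7,5,3,0.65,0.28
reference,eosinophil,d7,7.5,3,0.31,0.04
reference,eosinophil,d7,7.7,3,0.26,0.13
reference,eosinophil,d7,10,3,0.68,0.21
reference,eosinophil,d7,15,3,0.29,0.03
reference,eosinophil,d7,20,3,0.31,0.05
reference,eosinophil,d14,5,3,1.61,0.17
reference,eosinophil,d14,7.5,3,0.56,0.18
reference,eosinophil,d14,7.7,3,0.70,0.16
reference,eosinophil,d14,10,3,0.28,0.05
reference,eosinophil,d14,15,3,0.23,0.01
reference,eosinophil,d14,20,3,0.44,0.23
reference,eosinophil,d30,5,3,0.55,0.12
reference,eosinophil,d30,7.5,3,0.84,0.12
reference,eosinophil,d30,7.7,3,0.63,0.19
reference,eosinophil,d30,10,3,0.61,0.02
reference,eosinophil,d30,15,3,1.18,0.27
reference,eosinophil,d30,20,3,1.39,0.13
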