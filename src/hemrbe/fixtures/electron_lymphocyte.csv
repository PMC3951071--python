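arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,lymphocyte,pre,0,24,1.00,0.05
reference,lymphocyte,4h,5,3,0.44,0.22
reference,lymphocyte,4h,7.5,3,0.44,0.06
reference,lymphocyte,4h,7.7,3,0.47,0.08
reference,lymphocyte,4h,10,3,0.49,0.05
reference,lymphocyte,4h,15,3,0.45,0.06
reference,lymphocyte,4h,20,3,0.23,0.02
reference,lymphocyte,d1,5,3,0.59,0.08
reference,lymphocyte,d1,7.5,3,0.42,0.04
reference,lymphocyte,d1,7.7,3,0.41,0.08
reference,lymphocyte,d1,10,3,0.40,0.01
reference,lymphocyte,d1,15,3,0.25,0.03
reference,lymphocyte,d1,20,3,0.23,0.06
reference,lymphocyte,d7,5,3,0.82,0.09
reference,lymphocyte,d7,7.5,3,0.71,0.13
reference,lymphocyte,d7,7.7,3,0.29,0.05
reference,lymphocyte,d7,10,3,0.76,0.06
reference,lymphocyte,d7,15,3,0.51,0.06
reference,lymphocyte,d7,20,3,0.41,0.07
reference,lymphocyte,d14,5,3,1.09,0.04
reference,lymphocyte,d14,7.5,3,0.65,0.10
reference,lymphocyte,d14,7.7,3,0.77,0.07
reference,lymphocyte,d14,10,3,0.77,0.11
reference,lymphocyte,d14,15,3,0.63,0.02
reference,lymphocyte,d14,20,3,0.46,0.04
reference,lymphocyte,d30,5,3,0.69,0.03
reference,lymphocyte,d30,7.5,3,0.80,0.14
reference,lymphocyte,d30,7.7,3,0.89,0.14
reference,lymphocyte,d30,10,3,0.69,0.07
reference,lymphocyte,d30,15,3,0.79,0.04
reference,lymphocyte,d30,20,3,0.61,0.08
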