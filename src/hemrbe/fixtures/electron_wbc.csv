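arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,WBC,pre,0,24,1.00,0.05
reference,WBC,4h,5,3,0.83,0.05
reference,WBC,4h,7.5,3,0.61,0.09
reference,WBC,4h,7.7,3,0.80,0.10
reference,WBC,4h,10,3,0.54,0.04
reference,WBC,4h,15,3,0.76,0.02
reference,WBC,4h,20,3,0.53,0.04
reference,WBC,d1,5,3,0.96,0.18
reference,WBC,d1,7.5,3,0.45,0.07
reference,WBC,d1,7.7,3,0.59,0.03
reference,WBC,d1,10,3,0.44,0.00
reference,WBC,d1,15,3,0.58,0.14
reference,WBC,d1,20,3,0.33,0.04
reference,WBC,d7,5,3,0.85,0.04
reference,WBC,d7,7.5,3,0.76,0.16
reference,WBC,d7,7.7,3,0.60,0.06
reference,WBC,d7,10,3,0.77,0.02
reference,WBC,d7,15,3,0.56,0.06
reference,WBC,d7,20,3,0.47,0.07
reference,WBC,d14,5,3,1.18,0.02
reference,WBC,d14,7.5,3,1.01,0.32
reference,WBC,d14,7.7,3,1.02,0.04
reference,WBC,d14,10,3,0.79,0.05
reference,WBC,d14,15,3,0.56,0.15
reference,WBC,d14,20,3,0.59,0.07
reference,WBC,d30,5,3,0.56,0.12
reference,WBC,d30,7.5,3,1.07,0.15
reference,WBC,d30,7.7,3,0.75,0.11
reference,WBC,d30,10,3,0.78,0.02
reference,WBC,d30,15,3,0.65,0.05
reference,WBC,d30,20,3,0.74,0.08
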