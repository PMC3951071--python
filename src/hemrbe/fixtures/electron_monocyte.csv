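arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,monocyte,pre,0,24,1.00,0.08
reference,monocyte,4h,5,3,0.49,0.09
reference,monocyte,4h,7.5,3,0.45,0.06
reference,monocyte,4h,7.7,3,0.55,0.10
reference,monocyte,4h,10,3,0.34,0.09
reference,monocyte,4h,15,3,0.35,0.01
reference,monocyte,4h,20,3,0.26,0.07
reference,monocyte,d1,5,3,0.67,0.15
reference,monocyte,d1,7.5,3,0.44,0.13
reference,monocyte,d1,7.7,3,0.54,0.13
reference,monocyte,d1,10,3,0.42,0.08
reference,monocyte,d1,15,3,0.48,0.15
reference,monocyte,d1,20,3,0.29,0.08
reference,monocyte,d7,5,3,1.03,0.06
reference,monocyte,d7,7.5,3,0.90,0.19
reference,monocyte,d7,7.7,3,2.47,0.84
reference,monocyte,d7,10,3,0.62,0.02
reference,monocyte,d7,15,3,1.27,0.32
reference,monocyte,d7,20,3,0.61,0.06
reference,monocyte,d14,5,3,0.98,0.19
reference,monocyte,d14,7.5,3,1.12,0.14
reference,monocyte,d14,7.7,3,0.84,0.23
reference,monocyte,d14,10,3,0.77,0.20
reference,monocyte,d14,15,3,0.75,0.09
reference,monocyte,d14,20,3,0.56,0.16
reference,monocyte,d30,5,3,0.44,0.05
reference,monocyte,d30,7.5,3,1.62,0.68
reference,monocyte,d30,7.7,3,0.72,0.16
reference,monocyte,d30,10,3,0.72,0.18
reference,monocyte,d30,15,3,0.50,0.04
reference,monocyte,d30,20,3,0.75,0.16
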