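arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,neutrophil,pre,0,24,1.00,0.10
reference,neutrophil,4h,5,3,1.19,0.08
reference,neutrophil,4h,7.5,3,0.72,0.11
reference,neutrophil,4h,7.7,3,1.42,0.19
reference,neutrophil,4h,10,3,0.59,0.10
reference,neutrophil,4h,15,3,1.37,0.16
reference,neutrophil,4h,20,3,0.76,0.07
reference,neutrophil,d1,5,3,1.59,0.52
reference,neutrophil,d1,7.5,3,0.47,0.08
reference,neutrophil,d1,7.7,3,0.86,0.06
reference,neutrophil,d1,10,3,0.46,0.02
reference,neutrophil,d1,15,3,1.10,0.33
reference,neutrophil,d1,20,3,0.42,0.06
reference,neutrophil,d7,5,3,0.87,0.02
reference,neutrophil,d7,7.5,3,0.84,0.21
reference,neutrophil,d7,7.7,3,0.84,0.14
reference,neutrophil,d7,10,3,0.82,0.04
reference,neutrophil,d7,15,3,0.56,0.08
reference,neutrophil,d7,20,3,0.54,0.07
reference,neutrophil,d14,5,3,1.27,0.02
reference,neutrophil,d14,7.5,3,1.66,0.75
reference,neutrophil,d14,7.7,3,1.34,0.03
reference,neutrophil,d14,10,3,0.89,0.11
reference,neutrophil,d14,15,3,0.46,0.02
reference,neutrophil,d14,20,3,0.82,0.13
reference,neutrophil,d30,5,3,0.52,0.14
reference,neutrophil,d30,7.5,3,1.52,0.10
reference,neutrophil,d30,7.7,3,0.72,0.10
reference,neutrophil,d30,10,3,0.99,0.06
reference,neutrophil,d30,15,3,0.60,0.07
reference,neutrophil,d30,20,3,1.01,0.07
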