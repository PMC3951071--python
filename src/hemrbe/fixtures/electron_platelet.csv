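arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,platelet,pre,0,24,1.00,0.05
reference,platelet,4h,5,3,0.46,0.23
reference,platelet,4h,7.5,3,1.10,0.10
reference,platelet,4h,7.7,3,1.34,0.03
reference,platelet,4h,10,3,1.14,0.13
reference,platelet,4h,15,3,1.27,0.04
reference,platelet,4h,20,3,1.13,0.10
reference,platelet,d1,5,3,1.23,0.09
reference,platelet,d1,7.5,3,1.05,0.05
reference,platelet,d1,7.7,3,1.22,0.03
reference,platelet,d1,10,3,1.02,0.07
reference,platelet,d1,15,3,0.79,0.02
reference,platelet,d1,20,3,0.96,0.07
reference,platelet,d7,5,3,1.06,0.28
reference,platelet,d7,7.5,3,0.71,0.06
reference,platelet,d7,7.7,3,0.98,0.09
reference,platelet,d7,10,3,0.81,0.17
reference,platelet,d7,15,3,0.70,0.07
reference,platelet,d7,20,3,0.76,0.09
reference,platelet,d14,5,3,0.66,0.17
reference,platelet,d14,7.5,3,0.55,0.06
reference,platelet,d14,7.7,3,0.63,0.03
reference,platelet,d14,10,3,0.69,0.08
reference,platelet,d14,15,3,0.66,0.05
reference,platelet,d14,20,3,0.48,0.21
reference,platelet,d30,5,3,0.61,0.12
reference,platelet,d30,7.5,3,1.09,0.10
reference,platelet,d30,7.7,3,1.15,0.15
reference,platelet,d30,10,3,0.94,0.12
reference,platelet,d30,15,3,0.70,0.23
reference,platelet,d30,20,3,1.05,0.03
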