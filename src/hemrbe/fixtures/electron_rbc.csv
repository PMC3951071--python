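arm,cell_type,timepoint,dose_gy,n,mean_fraction,se_fraction
reference,RBC,pre,0,24,1.00,0.02
reference,RBC,4h,5,3,1.22,0.04
reference,RBC,4h,7.5,3,1.15,0.02
reference,RBC,4h,7.7,3,0.93,0.02
reference,RBC,4h,10,3,1.06,0.01
reference,RBC,4h,15,3,1.17,0.01
reference,RBC,4h,20,3,1.13,0.07
reference,RBC,d1,5,3,1.10,0.06
reference,RBC,d1,7.5,3,1.37,0.02
reference,RBC,d1,7.7,3,0.92,0.03
reference,RBC,d1,10,3,1.26,0.08
reference,RBC,d1,15,3,1.11,0.05
reference,RBC,d1,20,3,1.14,0.06
reference,RBC,d7,5,3,1.08,0.03
reference,RBC,d7,7.5,3,1.36,0.01
reference,RBC,d7,7.7,3,0.92,0.04
reference,RBC,d7,10,3,1.28,0.05
reference,RBC,d7,15,3,0.98,0.02
reference,RBC,d7,20,3,1.21,0.03
reference,RBC,d14,5,3,1.14,0.05
reference,RBC,d14,7.5,3,1.21,0.04
reference,RBC,d14,7.7,3,0.90,0.05
reference,RBC,d14,10,3,1.16,0.06
reference,RBC,d14,15,3,1.01,0.00
reference,RBC,d14,20,3,1.14,0.02
reference,RBC,d30,5,3,0.75,0.12
reference,RBC,d30,7.5,3,1.10,0.02
reference,RBC,d30,7.7,3,0.90,0.02
reference,RBC,d30,10,3,1.11,0.06
reference,RBC,d30,15,3,1.04,0.04
reference,RBC,d30,20,3,1.19,0.03
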