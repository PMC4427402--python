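subject_id,group,age,sex,FVC_L,FEV1_L,FEV1_FVC_pct,ci_mean,ci_sem,speed_mean,speed_sem
COPD1,COPD,74,F,1.68,0.59,35,0.533,0.028,0.129,0.007
COPD2,COPD,72,F,1.93,1.05,54,0.442,0.022,0.156,0.007
COPD3,COPD,57,F,1.89,0.73,39,0.317,0.04,0.118,0.01
COPD4,COPD,63,M,2.6,1.56,60,0.352,0.062,0.252,0.029
COPD5,COPD,67,F,1,0.75,75,0.304,0.039,0.135,0.008
CTRL1,control,41,M,NA,NA,NA,0.298,0.02,0.154,0.006
CTRL2,control,53,M,NA,NA,NA,0.144,0.013,0.212,0.005
CTRL3,control,26,M,NA,NA,NA,0.265,0.045,0.277,0.017
CTRL4,control,29,F,NA,NA,NA,0.191,0.045,0.272,0.028
CTRL5,control,64,F,NA,NA,NA,0.194,0.031,0.192,0.011
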