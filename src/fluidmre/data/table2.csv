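entity,study,role,control_tag,subregion,c_mean,c_sd,fluidity_mean,fluidity_sd,n
Liver - HEM,Shahryari 2019,tumor,,,1.97,0.45,0.21,0.38,11
Liver - HEM,Shahryari 2019,control,DTT,,1.37,0.13,-0.24,0.04,11
Liver - HCA,Shahryari 2019,tumor,,,1.41,0.21,-0.16,0.15,15
Liver - HCA,Shahryari 2019,control,DTT,,1.38,0.12,-0.16,0.08,15
Liver - FNH,Shahryari 2019,tumor,,,2.08,0.96,-0.07,0.31,10
Liver - FNH,Shahryari 2019,control,DTT,,1.40,0.12,-0.16,0.05,10
Liver - CCA,Shahryari 2019,tumor,,,2.57,0.90,0.58,0.32,12
Liver - CCA,Shahryari 2019,control,DTT,,1.72,0.29,-0.16,0.13,12
Liver - HCC,Shahryari 2019,tumor,,,2.54,0.64,0.53,0.37,22
Liver - HCC,Shahryari 2019,control,DTT,,1.97,0.49,0.03,0.20,22
Brain - MEN,Streitberger 2020,tumor,,,1.40,0.32,0.27,0.17,9
Brain - MEN,Streitberger 2020,control,CLH,,1.39,0.05,-0.26,0.09,9
Brain - GB,Streitberger 2020,tumor,,,1.07,0.28,-0.54,0.13,9
Brain - GB,Streitberger 2020,control,CLH,,1.42,0.18,-0.17,0.05,9
Pancreas Ca 1,Zhu 2020,tumor,,,2.35,0.39,0.53,0.17,40
Pancreas Ca 1,Zhu 2020,control,HV,,1.32,0.05,0.03,0.05,10
Pancreas Ca 2,Marticorena 2020,tumor,,,2.08,0.38,0.63,0.09,72
Pancreas Ca 2,Marticorena 2020,control,HV,,1.28,0.14,-0.01,0.09,30
Prostate PCa 1,Li Guo 2021,tumor,,,3.4,0.6,0.66,0.25,73
Prostate PCa 1,Li Guo 2021,control,HV,PZ,2.1,0.24,0.02,0.13,53
Prostate PCa 1,Li Guo 2021,control,HV,TZ,2.2,0.1,0.14,0.13,53
Prostate PCa 2,Asbach 2020,tumor,,,3.1,0.6,0.40,0.13,14
Prostate PCa 2,Asbach 2020,control,BPH,PZ,2.8,0.4,0.15,0.25,25
Prostate PCa 2,Asbach 2020,control,BPH,TZ,2.8,0.3,0.15,0.13,25
Colorectal Ca,Hu Guo 2021,tumor,,,2.3,0.5,0.71,0.36,80
Colorectal Ca,Hu Guo 2021,control,DTT,,1.3,0.1,-0.087,0.10,80
Colorectal Ca,Hu Guo 2021,control,HV,,1.4,0.1,-0.06,0.13,12
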