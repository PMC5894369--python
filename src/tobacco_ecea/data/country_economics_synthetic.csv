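country,gini,mean_income,mix_copd,mix_stroke,mix_heart_disease,mix_cancers,cost_copd,cost_stroke,cost_heart_disease,cost_cancers
India,0.35,5000,0.30,0.17,0.23,0.30,1500,2500,3000,4000
Indonesia,0.39,9000,0.30,0.17,0.23,0.30,1500,2500,3000,4000
Bangladesh,0.32,3000,0.30,0.17,0.23,0.30,1500,2500,3000,4000
Philippines,0.40,7000,0.30,0.17,0.23,0.30,1500,2500,3000,4000
Vietnam,0.35,5500,0.30,0.17,0.23,0.30,1500,2500,3000,4000
Armenia,0.32,8000,0.30,0.17,0.23,0.30,1500,2500,3000,4000
China,0.46,13000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Mexico,0.48,16000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Turkey,0.41,19000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Brazil,0.53,14000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Colombia,0.51,12000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Thailand,0.36,14500,0.30,0.17,0.23,0.30,3000,5000,6000,8000
Chile,0.47,21000,0.30,0.17,0.23,0.30,3000,5000,6000,8000
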