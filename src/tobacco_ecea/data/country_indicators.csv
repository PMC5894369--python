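country,income_class,male_population,smoking_prevalence_15_74,sticks_per_day,price_per_pack,tax_share,coverage_fraction,public_cost_share,poverty_headcount,smokers_total_metadata,in_catastrophic_subset
India,lower-middle,679,0.10,4,9.2,0.431,0.14,0.40,268,46,true
Indonesia,lower-middle,130,0.58,12,5.2,0.574,0.55,0.70,21,53,true
Bangladesh,lower-middle,81,0.28,8,3.4,0.770,0.26,0.36,28,25,true
Philippines,lower-middle,51,0.39,9,2.3,0.626,0.88,0.41,13,16,true
Vietnam,lower-middle,46,0.46,11,2.6,0.357,0.60,0.60,3,15,true
Armenia,lower-middle,1,0.53,24,3.1,0.350,0.28,1.00,0,1,false
China,upper-middle,709,0.52,14,2.8,0.508,0.97,0.26,25,291,true
Mexico,upper-middle,63,0.21,10,5.7,0.670,0.89,0.82,4,10,true
Turkey,upper-middle,39,0.39,18,10.3,0.821,0.85,0.98,0.3,12,false
Brazil,upper-middle,102,0.23,11,3.2,0.679,1.00,0.81,8,16,false
Colombia,upper-middle,24,0.18,8,2.2,0.495,0.91,1.00,3,3,false
Thailand,upper-middle,34,0.45,9,7.1,0.735,0.98,0.99,0.03,12,false
Chile,upper-middle,9,0.48,13,5.8,0.649,0.90,0.90,1,3,false
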