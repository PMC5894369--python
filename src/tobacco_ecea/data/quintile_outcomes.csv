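country,quintile,smokers,life_years,cost_averted,extra_tax
India,1,7.3,12.3,815,0.9
India,2,10.2,13.7,1040,1.6
India,3,9.5,9.4,773,1.9
India,4,9.1,6.0,547,2.5
India,5,10.0,3.2,313,3.5
India,total,46.1,44.7,3488,10.4
Indonesia,1,13.6,22.5,4120,2.1
Indonesia,2,12.0,15.8,3220,2.6
Indonesia,3,9.8,9.7,2770,3.4
Indonesia,4,9.7,6.3,2190,4.8
Indonesia,5,7.7,2.5,1050,3.4
Indonesia,total,52.9,56.8,13350,16.4
Bangladesh,1,3.0,5.4,81,0.2
Bangladesh,2,3.3,4.8,132,0.4
Bangladesh,3,3.1,3.3,97,0.5
Bangladesh,4,3.8,2.7,136,0.8
Bangladesh,5,3.0,1.1,61,0.8
Bangladesh,total,16.2,17.2,507,2.6
Philippines,1,3.0,5.3,647,0.2
Philippines,2,2.8,4.0,538,0.2
Philippines,3,2.6,2.8,405,0.3
Philippines,4,2.5,1.8,255,0.4
Philippines,5,2.2,0.8,119,0.3
Philippines,total,13.2,14.7,1964,1.5
Vietnam,1,3.7,5.6,296,0.5
Vietnam,2,3.3,4.1,233,0.4
Vietnam,3,2.6,2.4,199,0.4
Vietnam,4,2.6,1.5,118,0.5
Vietnam,5,2.4,0.7,73,0.5
Vietnam,total,14.6,14.3,919,2.4
Armenia,1,0.1,0.1,16,<0.1
Armenia,2,0.1,0.1,17,0.1
Armenia,3,0.1,0.1,16,0.1
Armenia,4,0.1,0.1,10,0.1
Armenia,5,0.1,<0.1,4,0.1
Armenia,total,0.6,0.5,63,0.3
China,1,63.9,83.6,33400,9.5
China,2,68.5,71.6,35500,14.2
China,3,63.1,49.2,24900,14.9
China,4,47.7,24.6,13400,12.7
China,5,47.7,12.0,6980,15
China,total,290.9,241,114180,66.3
Mexico,1,1.6,3.7,2170,0.3
Mexico,2,2.0,3.8,2260,0.5
Mexico,3,1.8,2.5,1980,0.4
Mexico,4,2.0,1.9,1600,0.8
Mexico,5,2.1,0.9,818,0.9
Mexico,total,9.5,12.8,8828,2.9
Turkey,1,1.8,3.3,445,0.6
Turkey,2,2.4,3.4,566,1.6
Turkey,3,2.9,3.1,524,2.8
Turkey,4,2.6,1.8,322,3.2
Turkey,5,1.9,0.7,132,2.9
Turkey,total,11.6,12.2,1989,11.1
Brazil,1,4.2,6.5,1850,0.2
Brazil,2,3.6,4.5,1720,0.5
Brazil,3,2.9,2.7,1170,0.8
Brazil,4,3.1,1.8,874,0.8
Brazil,5,2.0,0.6,295,0.7
Brazil,total,15.9,16.1,5909,3.1
Colombia,1,0.6,0.9,363,<0.1
Colombia,2,0.6,0.8,357,0.1
Colombia,3,0.7,0.7,264,0.1
Colombia,4,0.6,0.4,168,0.1
Colombia,5,0.6,0.2,93,0.1
Colombia,total,3.1,3.0,1245,0.4
Thailand,1,2.8,4.5,878,0.4
Thailand,2,3.3,4.2,836,0.8
Thailand,3,2.7,2.6,507,0.8
Thailand,4,2.3,1.5,290,1
Thailand,5,1.0,0.3,64,0.7
Thailand,total,12.0,13.0,2575,3.6
Chile,1,0.5,0.8,457,0.1
Chile,2,0.6,0.8,494,0.2
Chile,3,0.7,0.7,436,0.2
Chile,4,0.7,0.5,373,0.3
Chile,5,0.8,0.3,224,0.4
Chile,total,3.2,3.1,1984,1.3
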