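country,quintile,u5mr,coverage,births,cfr,cause:asphyxia,cause:congenital,cause:diarrhoea,cause:injury,cause:malaria,cause:other,cause:pneumonia,cause:preterm
Peru,1,9.0,0.58,120000.0,0.0002171988938149332,0.11879531988412408,0.13672025489037753,0.09041426116787898,0.07123136733662482,0.06280787441853522,0.18809258981652976,0.12382473264621782,0.20811359983971175
Peru,2,24.0,0.52,120000.0,0.00034049557292342784,0.11979716656340104,0.12600668056496875,0.09537343056067224,0.06764891368774904,0.06827054928807898,0.1896788470587183,0.13259046167819533,0.2006339505982164
Peru,3,24.0,0.46,120000.0,0.00034049557292342784,0.11979716656340104,0.12600668056496875,0.09537343056067224,0.06764891368774904,0.06827054928807898,0.1896788470587183,0.13259046167819533,0.2006339505982164
Peru,4,33.0,0.4,120000.0,0.0004458802332317503,0.12024783943968254,0.11983188874949777,0.09835220274520885,0.06550236207685174,0.07168154946067701,0.190392412446164,0.13796776207233155,0.19602398300958657
Peru,5,59.0,0.35,120000.0,0.0009709703543510518,0.12090508043063046,0.10308363720117523,0.10691196924379995,0.05935504022116905,0.08207916609443279,0.1914330440151649,0.15392583363042348,0.1823062291632042
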