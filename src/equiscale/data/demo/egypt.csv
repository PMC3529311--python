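country,quintile,u5mr,coverage,births,cfr,cause:asphyxia,cause:congenital,cause:diarrhoea,cause:injury,cause:malaria,cause:other,cause:pneumonia,cause:preterm
Egypt,1,18.9,0.6,380000.0,0.0002922364273767628,0.11949145031437072,0.12959053064234885,0.09368563071532068,0.06886692959695465,0.0663818228357485,0.18919479633108693,0.1295814876403238,0.20320735192384592
Egypt,2,27.2,0.65,380000.0,0.00037476073048913215,0.11997044401207188,0.12378922295948207,0.0964327054803033,0.06688513032183024,0.0694720043111551,0.18995320301911384,0.13449278045059795,0.19900450944544568
Egypt,3,32.2,0.64,380000.0,0.00043532184322452906,0.12021239666277558,0.12037297436947324,0.09808752088904467,0.06569293681320859,0.07137435232097979,0.19033629471606134,0.13748643511419795,0.1964370891142589
Egypt,4,36.1,0.57,380000.0,0.0004892656223019051,0.12037663598762427,0.1177496019798059,0.0993774732569473,0.06476444234005868,0.07287924577165121,0.1905963403137384,0.1398388333177828,0.19441742703239154
Egypt,5,49.0,0.524,380000.0,0.0007199164389269049,0.12076614865254784,0.1093321954000617,0.10363302154744432,0.061706377121932346,0.0779864008217331,0.19121306869986743,0.14772037490904558,0.1876424128473678
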