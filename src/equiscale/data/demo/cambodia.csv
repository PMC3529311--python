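country,quintile,u5mr,coverage,births,cfr,cause:asphyxia,cause:congenital,cause:diarrhoea,cause:injury,cause:malaria,cause:other,cause:pneumonia,cause:preterm
Cambodia,1,30.0,0.55,74000.0,0.0004075559851286877,0.1201102736494395,0.12186881261952047,0.09735949559940375,0.06621728493065877,0.07053356607801288,0.19017459994494587,0.13616608800906663,0.19756987916895205
Cambodia,2,49.0,0.44,74000.0,0.0007199164389269049,0.12076614865254784,0.1093321954000617,0.10363302154744432,0.061706377121932346,0.0779864008217331,0.19121306869986743,0.14772037490904558,0.1876424128473678
Cambodia,3,68.0,0.35,74000.0,0.001270661892253027,0.12090845647250063,0.09766747463964202,0.10984098194367632,0.05725786218970307,0.08585949184711078,0.1914383894147927,0.15957257099173916,0.17745477250083538
Cambodia,4,83.0,0.26,74000.0,0.0019880091748988834,0.12065974816902263,0.08907774055015363,0.1146603850768363,0.05381250357079465,0.0923562174383613,0.19104460126761916,0.1690914501991476,0.1692973537280649
Cambodia,5,90.0,0.2,74000.0,0.0024487713459479666,0.12043613617612327,0.08525566061101424,0.11687671042995876,0.052229678389254484,0.09546866375325284,0.1906905489455285,0.1735706515954954,0.16547195009937252
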