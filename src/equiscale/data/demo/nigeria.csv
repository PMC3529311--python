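country,quintile,u5mr,coverage,births,cfr,cause:asphyxia,cause:congenital,cause:diarrhoea,cause:injury,cause:malaria,cause:other,cause:pneumonia,cause:preterm
Nigeria,1,87.0,0.45,1200000.0,0.0022395819008543053,0.12054027299462701,0.08687921361117919,0.11592969303327921,0.05290591648686623,0.0941286398749124,0.1908554322414928,0.17164854115638276,0.16711229060126054
Nigeria,2,129.0,0.38,1200000.0,0.007749371557399214,0.11798636634600153,0.06609571840435749,0.12871093529887745,0.0437766399658388,0.11366409020676416,0.1868117467145024,0.1987473035618425,0.14420719950181568
Nigeria,3,165.0,0.3,1200000.0,0.02172794560845532,0.11406210117258922,0.05148435314573781,0.13862092469715093,0.03664490166217155,0.13155453630651712,0.18059832685659957,0.22189585613856924,0.12513900002066455
Nigeria,4,212.0,0.21,1200000.0,0.07269610829888852,0.10696522572029878,0.036417108584001455,0.149680614648124,0.02847524322551254,0.15605089929707694,0.16936160739047307,0.25112953870977256,0.1019197624247407
Nigeria,5,219.0,0.15,1200000.0,0.0848774143521082,0.10575288285420505,0.034523490295635374,0.1511246629391141,0.027375168441546385,0.15977770761118346,0.16744206451915802,0.25533341136912713,0.09867061197003035
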