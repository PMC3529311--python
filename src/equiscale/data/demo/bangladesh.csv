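country,quintile,u5mr,coverage,births,cfr,cause:asphyxia,cause:congenital,cause:diarrhoea,cause:injury,cause:malaria,cause:other,cause:pneumonia,cause:preterm
Bangladesh,1,43.0,0.37,620000.0,0.0006015625571941218,0.12061441090249081,0.11319745265105244,0.10165642758018983,0.06312582982095234,0.07558646356250688,0.1909728172622771,0.14403608790785213,0.19081051031267843
Bangladesh,2,62.0,0.33,620000.0,0.001062087066283951,0.12091899202118919,0.10125638096259097,0.10789093264818753,0.05865378430855012,0.08332922076595582,0.19145507070021625,0.15580199559784638,0.18069362299546365
Bangladesh,3,83.0,0.29,620000.0,0.0019880091748988834,0.12065974816902263,0.08907774055015363,0.1146603850768363,0.05381250357079465,0.0923562174383613,0.19104460126761916,0.1690914501991476,0.1692973537280649
Bangladesh,4,85.0,0.27,620000.0,0.002110076146498548,0.12060278597770993,0.08797364464000901,0.11529595969674698,0.053358519069300274,0.0932403742699141,0.19095441113137407,0.17036913972788845,0.16820516548705722
Bangladesh,5,86.0,0.26,620000.0,0.0021738718787494287,0.12057222221295169,0.08742522177969642,0.11561306025646986,0.053132042889747384,0.09368399570306908,0.19090601850384017,0.17100863220542878,0.1676588064487966
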