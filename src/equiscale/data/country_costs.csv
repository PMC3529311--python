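country,column,u5mr,antibiotic_cost,nonantibiotic_cost,total_cost
Nigeria,overall,189.00,0.27,2.52,2.79
Nigeria,1,87.00,0.27,1.43,1.70
Nigeria,2,129.00,0.27,1.87,2.14
Nigeria,3,165.00,0.27,2.26,2.53
Nigeria,4,212.00,0.27,2.76,3.03
Nigeria,5,219.00,0.27,2.84,3.11
Egypt,overall,36.00,0.27,0.88,1.15
Egypt,1,18.90,0.27,0.70,0.97
Egypt,2,27.20,0.27,0.79,1.06
Egypt,3,32.20,0.27,0.84,1.11
Egypt,4,36.10,0.27,0.88,1.15
Egypt,5,49.00,0.27,1.02,1.29
Bangladesh,overall,61.00,0.27,1.15,1.42
Bangladesh,1,43.00,0.27,0.95,1.22
Bangladesh,2,62.00,0.27,1.16,1.43
Bangladesh,3,83.00,0.27,1.38,1.65
Bangladesh,4,85.00,0.27,1.40,1.67
Bangladesh,5,86.00,0.27,1.41,1.68
Cambodia,overall,54.00,0.27,1.07,1.34
Cambodia,1,30.00,0.27,0.82,1.09
Cambodia,2,49.00,0.27,1.02,1.29
Cambodia,3,68.00,0.27,1.22,1.49
Cambodia,4,83.00,0.27,1.38,1.65
Cambodia,5,90.00,0.27,1.46,1.73
Peru,overall,27.00,0.27,0.78,1.05
Peru,1,9.00,0.27,0.59,0.86
Peru,2,24.00,0.27,0.75,1.02
Peru,3,24.00,0.27,0.75,1.02
Peru,4,33.00,0.27,0.85,1.12
Peru,5,59.00,0.27,1.13,1.40
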