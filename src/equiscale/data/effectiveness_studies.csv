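location,year,u5mr,effectiveness
Tanzania,1986,161.40,30.10
Nepal,1989,126.30,84.00
India,1990,114.80,49.10
Pakistan,1990,123.60,55.00
India,1991,111.90,26.00
Nepal,1991,122.00,30.00
Bangladesh,1992,132.10,50.00
India,1993,105.60,27.80
Philippines,1998,43.10,35.00
Global,2012,0.00,100.00
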