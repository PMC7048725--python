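locality_number,name,latitude,longitude,n_samples,cluster
Loc 1,Paraguay,-27.275,-57.684,5,P-RP
Loc 2,"Isla, Rio Parana",-27.314,-58.646,36,P-RP
Loc 3,"EBCO, Corrientes",-27.550,-58.679,40,F-Ch-C
Loc 4,"PN Chaco, Chaco",-26.794,-59.618,9,F-Ch-C
Loc 5,"Guaycolec, Formosa",-25.985,-58.161,12,F-Ch-C
Loc 6,"San Alonso, Corrientes",-28.306,-57.456,10,F-Ch-C
Loc 7,"Garupa, Misiones",-27.467,-55.827,6,M-RU
Loc 8,"Yacutinga Lodge, Misiones",-25.574,-54.075,6,M-RU
Loc 9,"PP Pinalito, Misiones",-26.500,-53.833,11,M-RU
Loc 10,"Yapeyu, Corrientes",-29.445,-56.800,9,M-RU
Loc 11,"PP Lago Urugua-i, Misiones",-25.921,-54.419,9,M-RU
Loc 12,"Azara, Misiones",-27.984,-55.787,5,M-RU
Loc 13,"Apostoles, Misiones",-27.910,-55.761,4,M-RU
Loc 14,"Reserva Urutau EBY",-27.518,-55.788,4,M-RU
Loc 15,"Sta Cecilia, Misiones",-27.429,-55.710,12,M-RU
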