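individual_id,group,best_locality,locality_score,locality_flagged_unassigned,best_cluster,cluster_score,cluster_flagged_unassigned
Guira-Oga 1,confiscated,Loc 6,96.46,0,F-Ch-C,86.07,0
Guira-Oga 2,confiscated,Loc 5,84.56,0,F-Ch-C,99.84,0
Guira-Oga 3,confiscated,Loc 3,44.28,1,F-Ch-C,98.38,0
Guira-Oga 4,confiscated,Loc 2,75.75,0,P-RP,93.51,0
Guira-Oga 5,confiscated,Loc 7,38.42,1,M-RU,96.57,0
Guira-Oga 6,confiscated,Loc 3,39.59,1,F-Ch-C,75.37,0
Guira-Oga 7,confiscated,Loc 3,49.6,1,F-Ch-C,70.25,0
Guira-Oga 8,confiscated,Loc 3,98.06,0,F-Ch-C,99.98,0
Guira-Oga 9,confiscated,Loc 5,70.05,0,F-Ch-C,100,0
Guira-Oga 10,confiscated,Loc 2,98.99,0,P-RP,99.59,0
Guira-Oga 11,confiscated,Loc 2,44.47,1,P-RP,99.31,0
Guira-Oga 12,confiscated,Loc 3,49.41,1,F-Ch-C,86.05,0
Guira-Oga 13,confiscated,Loc 3,96.65,0,F-Ch-C,93.83,0
Guira-Oga 14,confiscated,Loc 3,99.81,0,F-Ch-C,96.88,0
Guira-Oga 15,confiscated,Loc 3,96.54,0,F-Ch-C,88.15,0
Guira-Oga 16,confiscated,Loc 13,74.15,0,M-RU,99.97,0
Guira-Oga 17,confiscated,Loc 1,89.15,0,P-RP,99.87,0
Esmeralda 1,confiscated,Loc 10,53.12,1,M-RU,99.37,0
Esmeralda 2,confiscated,Loc 3,89.16,0,F-Ch-C,81,0
Esmeralda 3,confiscated,Loc 3,62.74,0,F-Ch-C,56.68,1
Esmeralda 4,confiscated,Loc 3,98.56,0,F-Ch-C,97.92,0
Esmeralda 5,confiscated,Loc 6,74.28,0,F-Ch-C,99.15,0
Found dead in Loc 13 Misiones,corpse,Loc 5,80.29,0,F-Ch-C,98.04,0
Found dead in Posadas Misiones,corpse,Loc 15,54.69,1,M-RU,69.54,1
Found dead in San Antonio Misiones,corpse,Loc 12,42.38,1,M-RU,99.67,0
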