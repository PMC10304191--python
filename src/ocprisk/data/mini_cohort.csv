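id,village,sex,age,weight,smoking,alcohol,cons_meat,cons_cucumbers,cons_tomatoes,cons_peppers,cons_apples,cons_pears,cons_milk,rs861539,rs1799782,rs25487,rs13181,rs17861084,rs8192718,rs186133763,rs11592737,rs1601993659,rs1183423000,rs1138272,rs1695,rs1871042,rs138002121,rs1041740,rs2237329,rs713041,rs41303970,rs12524550,rs3799694,rs524553
MC-001,Kyzylkairat,F,50,70,0,0,0.1,0.1,0.2,0.05,0.3,0.1,0.5,0,0,0,0,0,0,0,0,+,+,0,0,0,0,0,0,0,0,0,0,0
MC-002,Kyzylkairat,M,45,80,1,1,0.2,0.1,0.2,0.05,0.2,0.1,0.4,1,0,1,0,0,0,0,0,+,-,0,1,0,0,1,0,1,0,0,0,0
MC-003,Kyzylkairat,F,60,65,0,1,0.1,0.2,0.1,0.1,0.4,0.2,0.6,2,1,2,1,1,1,1,1,-,-,1,2,1,1,2,1,2,1,1,1,1
MC-004,Kyzylkairat,M,35,90,1,0,0.3,0.1,0.3,0.0,0.1,0.0,0.2,0,1,0,1,0,0,0,0,+,+,0,0,1,0,0,0,1,0,0,1,0
MC-005,Belbulak,F,55,68,0,0,0.1,0.05,0.1,0.02,0.4,0.15,0.3,1,0,1,0,0,0,0,1,-,+,0,0,0,1,1,0,1,0,0,0,0
MC-006,Belbulak,M,48,78,0,0,0.2,0.1,0.1,0.03,0.3,0.2,0.4,0,0,2,0,0,0,0,0,+,-,0,1,0,0,0,0,1,1,0,0,0
MC-007,Belbulak,F,42,62,1,1,0.1,0.05,0.15,0.02,0.5,0.1,0.3,0,0,0,0,2,2,2,0,+,+,2,0,0,2,0,2,0,0,2,0,0
MC-008,Belbulak,F,70,60,0,0,0.05,0.1,0.1,0.05,0.2,0.1,0.5,1,1,1,1,0,0,0,0,-,-,0,0,2,0,1,0,1,0,0,0,1
MC-009,Beskainar,M,52,82,1,1,0.15,0.2,0.5,0.1,0.6,0.7,0.4,0,0,1,0,0,0,0,0,+,+,0,0,0,0,2,0,1,0,0,1,0
MC-010,Beskainar,F,58,72,0,0,0.1,0.25,0.4,0.15,0.5,0.6,0.5,2,0,0,0,0,0,0,0,+,-,0,1,1,0,0,1,1,0,0,0,0
MC-011,Beskainar,F,47,66,0,1,0.12,0.2,0.45,0.1,0.7,0.65,0.35,0,0,0,0,0,0,0,0,-,-,0,0,0,0,0,0,2,0,0,0,0
MC-012,Beskainar,M,63,75,1,0,0.18,0.15,0.5,0.12,0.55,0.7,0.45,1,1,1,1,1,0,0,0,+,+,0,0,0,1,1,0,0,1,0,0,0
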