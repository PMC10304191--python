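rsid,gene,cluster,marker_model,risk_allele
rs861539,XRCC3,repair,codominant,B
rs1799782,XRCC1,repair,codominant,B
rs25487,XRCC1,repair,codominant,B
rs13181,XPD,repair,codominant,B
rs17861084,CYP1A1,detox,codominant,B
rs8192718,CYP2B6,detox,codominant,B
rs186133763,CYP2D6,detox,codominant,B
rs11592737,CYP2C19,detox,codominant,B
rs1601993659,GSTT1,detox,dominant_deletion,-
rs1183423000,GSTM1,detox,dominant_deletion,-
rs1138272,GSTP1,detox,codominant,B
rs1695,GSTP1,detox,codominant,B
rs1871042,GSTP1,detox,codominant,B
rs138002121,SOD1,antioxidant,codominant,B
rs1041740,SOD1,antioxidant,codominant,B
rs2237329,NFE2L3,antioxidant,codominant,B
rs713041,GPX4,antioxidant,codominant,B
rs41303970,GCLM,antioxidant,codominant,B
rs12524550,GCLC,antioxidant,codominant,B
rs3799694,GCLC,antioxidant,codominant,B
rs524553,GCLC,antioxidant,codominant,B
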