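rsid,n_AA,n_AB,n_BB,n_positive,n_null
rs861539,95,38,18,NA,NA
rs1799782,102,41,8,NA,NA
rs25487,50,63,38,NA,NA
rs13181,88,55,8,NA,NA
rs17861084,134,0,17,NA,NA
rs8192718,132,2,17,NA,NA
rs186133763,134,0,17,NA,NA
rs11592737,115,29,7,NA,NA
rs1601993659,NA,NA,NA,128,89
rs1183423000,NA,NA,NA,110,110
rs1138272,115,17,19,NA,NA
rs1695,87,50,14,NA,NA
rs1871042,72,48,31,NA,NA
rs138002121,133,1,17,NA,NA
rs1041740,59,55,37,NA,NA
rs2237329,106,23,22,NA,NA
rs713041,21,97,33,NA,NA
rs41303970,117,27,7,NA,NA
rs12524550,131,3,17,NA,NA
rs3799694,81,55,15,NA,NA
rs524553,126,23,2,NA,NA
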