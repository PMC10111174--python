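code,latitude,longitude,sample_year,cluster,n,N_A,P_A,H_O,H_E,F_IS
Vuo,60°31′,21°15′,2012,V,4,26,1,0.23,0.25,0.34
Nad,60°28′,22°01′,2012,V,22,32,0,0.17,0.20,0.35
Bla,59°59′,18°16′,2012,IV,28,30,1,0.19,0.25,0.39
Ham,59°46′,17°35′,2012,IV,21,48,4,0.32,0.47,0.36
Tul42,58°59′,17°33′,2012,III,30,74,6,0.45,0.57,0.32
Tul3,58°58′,17°37′,2012,III,27,65,1,0.33,0.44,0.37
Tul11,58°58′,17°37′,2012,III,24,60,0,0.39,0.50,0.31
Get,58°40′,16°19′,2012,III,26,70,4,0.42,0.55,0.34
Ver,57°44′,16°31′,2012,II,34,81,3,0.40,0.58,0.37
Em,57°08′,16°29′,2012,II,28,77,4,0.51,0.61,0.30
Res,56°32′,16°31′,2012,II,27,89,14,0.47,0.61,0.33
Vad,56°26′,12°34′,1991,,4,21,2,,0.44,0.35
Hal,56°10′,15°50′,2015,I,19,53,2,0.34,0.43,0.31
Lis,56°02′,14°47′,2015,I,24,43,2,0.29,0.43,0.40
Sol,55°56′,11°55′,1991,,5,24,1,,0.56,0.60
Ror,55°56′,11°46′,1991,,6,35,1,0.26,0.35,0.35
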