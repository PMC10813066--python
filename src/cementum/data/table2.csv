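specimen_id,fdi,ba_code,sex,age_class,etiology,wear_deg,wear_dir,wear_for,caries_si,caries_sta,pulp_exp,impacted,hc_score,fen,cal,nt,ant,max_thi_um,loc_max,loc_min,pref,shape_note,note_verbatim,roi_loc,max_ve_um,aspect,roi_note,of_loc,of_max_ve_um,of_aspect,of_note,excluded
Sp755,13,URL,F,20-39,IMP,1,1,1,,,none,1,3.3.m,0,0,NA,0,1000,2d,<,yes,Nds,Nds (d),2d,690,+S2,Nds,2m,100,-R2,,0
Sp755,23,ULC,F,20-39,IMP,1,1,1,,,none,1,3.3.m,0,0,NA,0,1070,2d,<,yes,NOD,NOD (d),2d,450,+S2,IL,2m,90,-R2,IL,0
Sp114,14,URP3,F,20-60,INF,0,0,0,1,4,M,0,3.4.M,1,0,0,1,1470,m,<,no,OG,OG,m,475,+S2,,,,,,0
Sp335,23,ULC,M,>18,INF,0,0,0,1,4,M,0,1.4.M,1,0,2,1,2160,<,>,no,RES,RES (>),<,250,+R2,,,,,,0
Sp914,43,LRC,M,20-39,INF,0,0,0,1,4,M,0,1.4.m,0,0,0,3,1950,d,m,no,none,-,d,450,+S2,,,,,,0
Sp1172,15,URP4,F,>30,INF,0,0,0,1,4,M,0,1.4.M,0,0,1d,1,1380,d,No,no,RES,RES (d),d,110,-S2,AF,m,220,-S2,AF,0
Sp17,15,URP4,F,20-39,HYPO,3,4,2,,,none,0,1.2.m,0,0,1d,1,1640,2m,<,no,FR,FR (2m),2m,160,-R2,FR,,,,,0
Sp20,35,LLP4,I,>20,HYPO,2,6,2,,,none,0,1.2.m,0,0,0,1,1310,1m,<,no,none,-,1m,180,-S2,IL,2d,150,+S2,CL,0
Sp173,45,LRP4,M,>60,HYPO,3,6,3,,,none,0,1.2.m,0,0,0,2,1470,1>,<,no,SE,SE,1>,170,-S1,CL,,,,,0
Sp914,34,LLP3,M,20-39,HYPO,2,1,1,,,none,0,1.2.m,0,0,0,3,1410,1d,No,no,none,-,1d,140,-S2,,,,,,0
Sp1230,34,LLP3,M,>20,HYPO,3,1,1,,,none,0,1.2.m,0,1,0,1,1240,1m,No,no,none,-,1m,110,-R2,,,,,,0
Sp1230,44,URP3,M,>20,HYPO,3,1,1,,,none,0,1.2.M,0,0,0,1,1280,1d,m,no,none,2 roots,,,,,,,,,1
Sp39,35,LLP4,F,20-49,HYPER,8,4,2,,,none,0,1.2.m,0,0,2,1,740,1m,No,yes,none,-,1m,400,+R2,,,,,,0
Sp199,11,URI1,M,>30,HYPER,6,6,4,,,none,0,1.2.m,0,0,0,1,1380,1>,<,yes,RES,RES (1<),1>,170,-R1,,,,,,0
Sp199,12,URI2,M,>30,HYPER,6,4,4,,,none,0,1.3.m,0,0,0,1,900,1>,<,yes,none,-,1>,230,+R1,IL,1<,350,+R1,,0
Sp335,13,URC,M,>18,HYPER,4,2,2,,,none,0,1.2.m,0,0,2,1,1970,1d,<,yes,FR,FR (1>m),1d,325,+R1,,,,,,0
Sp479,11,URI1,M,20-60,HYPER,7,2,2,,,none,0,3.2.M,0,0,0,1,1480,1>,<,yes,NOD,NOD (m>),1m>,665,+S2,NOD,,,,,0
Sp591,12,URI2,M,20-39,HYPER,5,4,6,,,none,0,1.1.m,0,0,1d,1,1510,1>,<,yes,FR,FR (1>),1d,192,-R2,FR,,,,,0
Sp810,13,URC,F,>20,HYPER,3,2,2,,,none,0,1.3.m,0,0,0,3,1030,1>,<,yes,none,-,1>,200,+R1,,,,,,0
Sp810,23,ULC,F,>20,HYPER,3,2,2,,,none,0,3.2.m,0,0,0,3,790,2>,<,yes,Nds,Nds (>),2>,475,+S2,Nds,,,,,0
Sp876,35,LLP4,M,>30,HYPER,6,2,6,,,none,0,1.2.m,0,1,2,2,1010,1>,<,yes,none,-,1>,250,+R2,,,,,,0
Sp914,33,LLC,M,20-39,HYPER,4,4,4,,,none,0,1.2.m,0,0,0,3,1270,1>,No,yes,none,-,1>,95,-R1,,,,,,0
Sp1010,44,LRP3,M,>30,HYPER,5,4,6,,,none,0,3.2.M,0,0,1d,3,2080,1d,m,yes,none,2 roots,,,,,,,,,1
Sp1172,24,ULP3,F,>30,HYPER,6,2,4,,,none,0,3.2.M,0,0,1d,1,1200,2d,<,yes,NOD,NOD (d),,,,,,,,,0
Sp1135,11,URI1,M,>30,HYPER,6,4,5,,,none,0,1.3.m,0,0,0,1,1180,1>d +2m,1<,yes,RID,RID (<),1m,300,+R1,,2<d,260,+R1,RID,0
Sp583,45,LRP4,F,>60,MIX,6,4,2,,,none,0,3.2.M,0,1,1d,2,2770,1,<,yes,LSP,LSP (1),2>,43,-S2,,,,,,0
Sp666,33,LLC,M,>30,MIX,7,5,6,2,2,none,0,3.2.M,0,1,1m,3,2350,1m,<,yes,NOD,"NOD, CAR (m)",1m,475,+S2,NOD,,,,,0
Sp709,31,LLI1,I,>20,MIX,6,6,4,,,none,0,3.1.m,0,1,0,3,1330,1<,No,yes,LSP,LPS (<),<,550,+R1,LSP,,,,,0
Sp735,45,LRP4,M,>20,MIX,4,6,3,2,4,C,0,1.2.M,0,0,1d,2,1230,1m,No,yes,CAR,CAR (m),1m,175,-R1,,d,118,-S2,IL,0
Sp876,44,LRP3,M,>30,MIX,0,0,0,1,4,M,0,1.4.m,0,1,0,2,1320,1d,No,yes,RES,RES (m<),1d,200,+R2,,,,,,0
Sp876,45,LRP4,M,>30,MIX,4,6,3,2,2,none,0,1.2.M,0,1,0,2,1670,1d,<,no,FR,FR (1>),2d,200,+R2,,,,,,0
Sp884,34,LLP3,F,>30,MIX,8,3,6,,,none,0,3.4.M,0,0,1m,1,1450,d,No,no,W,W,1d,370,+R2,,,,,,0
Sp884,35,LLP4,F,>30,MIX,8,7,6,,,W,0,3.4.M,0,0,1d,2,1590,d>,<,yes,OG,OG (>),>,310,+R2,,,,,,0
Sp914,35,LLP4,M,20-39,MIX,3,3,3,2,3,none,0,1.2.m,0,0,0,3,1100,1d,No,no,CAR,CAR (d),1d,375,+R2,,,,,,0
Sp1300,14,URP3,MD,MD,MIX,7,4,4,2,2,none,0,1.2.M,0,0,NA,2,1440,1m,>,no,CAR,CAR (m),2m,280,+R1,,,,,,0
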