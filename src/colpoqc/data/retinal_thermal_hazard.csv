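# Spectral hazard weighting nodes, 5-nm resolution, linear interpolation
# between nodes, zero outside the tabulated range.  Values follow the
# published lamp-safety weighting functions adopted by ANSI/IESNA RP-27
# and IEC 62471 (ACGIH/ICNIRP photobiological hazard functions).
wavelength_nm,weight
400,1
405,2
410,4
415,8
420,9
425,9.5
430,9.8
435,10
440,10
445,9.7
450,9.4
455,9
460,8
465,7
470,6.2
475,5.5
480,4.5
485,4
490,2.2
495,1.6
500,1
505,1
510,1
515,1
520,1
525,1
530,1
535,1
540,1
545,1
550,1
555,1
560,1
565,1
570,1
575,1
580,1
585,1
590,1
595,1
600,1
605,1
610,1
615,1
620,1
625,1
630,1
635,1
640,1
645,1
650,1
655,1
660,1
665,1
670,1
675,1
680,1
685,1
690,1
695,1
700,1
705,0.977237
710,0.954993
715,0.933254
720,0.912011
725,0.891251
730,0.870964
735,0.851138
740,0.831764
745,0.812831
750,0.794328
755,0.776247
760,0.758578
765,0.74131
770,0.724436
775,0.707946
780,0.691831
785,0.676083
790,0.660693
795,0.645654
800,0.630957
805,0.616595
810,0.60256
815,0.588844
820,0.57544
825,0.562341
830,0.549541
835,0.537032
840,0.524807
845,0.512861
850,0.501187
855,0.489779
860,0.47863
865,0.467735
870,0.457088
875,0.446684
880,0.436516
885,0.42658
890,0.416869
895,0.40738
900,0.398107
905,0.389045
910,0.380189
915,0.371535
920,0.363078
925,0.354813
930,0.346737
935,0.338844
940,0.331131
945,0.323594
950,0.316228
955,0.30903
960,0.301995
965,0.295121
970,0.288403
975,0.281838
980,0.275423
985,0.269153
990,0.263027
995,0.25704
1000,0.251189
1005,0.245471
1010,0.239883
1015,0.234423
1020,0.229087
1025,0.223872
1030,0.218776
1035,0.213796
1040,0.20893
1045,0.204174
1050,0.199526
1055,0.2
1060,0.2
1065,0.2
1070,0.2
1075,0.2
1080,0.2
1085,0.2
1090,0.2
1095,0.2
1100,0.2
1105,0.2
1110,0.2
1115,0.2
1120,0.2
1125,0.2
1130,0.2
1135,0.2
1140,0.2
1145,0.2
1150,0.2
1155,0.158866
1160,0.126191
1165,0.100237
1170,0.0796214
1175,0.0632456
1180,0.0502377
1185,0.0399052
1190,0.0316979
1195,0.0251785
1200,0.02
1205,0.02
1210,0.02
1215,0.02
1220,0.02
1225,0.02
1230,0.02
1235,0.02
1240,0.02
1245,0.02
1250,0.02
1255,0.02
1260,0.02
1265,0.02
1270,0.02
1275,0.02
1280,0.02
1285,0.02
1290,0.02
1295,0.02
1300,0.02
1305,0.02
1310,0.02
1315,0.02
1320,0.02
1325,0.02
1330,0.02
1335,0.02
1340,0.02
1345,0.02
1350,0.02
1355,0.02
1360,0.02
1365,0.02
1370,0.02
1375,0.02
1380,0.02
1385,0.02
1390,0.02
1395,0.02
1400,0.02
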