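# Spectral hazard weighting nodes, 5-nm resolution, linear interpolation
# between nodes, zero outside the tabulated range.  Values follow the
# published lamp-safety weighting functions adopted by ANSI/IESNA RP-27
# and IEC 62471 (ACGIH/ICNIRP photobiological hazard functions).
wavelength_nm,weight
300,0.01
305,0.01
310,0.01
315,0.01
320,0.01
325,0.01
330,0.01
335,0.01
340,0.01
345,0.01
350,0.01
355,0.01
360,0.01
365,0.01
370,0.01
375,0.01
380,0.01
385,0.013
390,0.025
395,0.05
400,0.1
405,0.2
410,0.4
415,0.8
420,0.9
425,0.95
430,0.98
435,1
440,1
445,0.97
450,0.94
455,0.9
460,0.8
465,0.7
470,0.62
475,0.55
480,0.45
485,0.4
490,0.22
495,0.16
500,0.1
505,0.0794328
510,0.0630957
515,0.0501187
520,0.0398107
525,0.0316228
530,0.0251189
535,0.0199526
540,0.0158489
545,0.0125893
550,0.01
555,0.00794328
560,0.00630957
565,0.00501187
570,0.00398107
575,0.00316228
580,0.00251189
585,0.00199526
590,0.00158489
595,0.00125893
600,0.001
605,0.001
610,0.001
615,0.001
620,0.001
625,0.001
630,0.001
635,0.001
640,0.001
645,0.001
650,0.001
655,0.001
660,0.001
665,0.001
670,0.001
675,0.001
680,0.001
685,0.001
690,0.001
695,0.001
700,0.001
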