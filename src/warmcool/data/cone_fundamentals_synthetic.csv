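wavelength_nm,l,m,s
390,0.00000384,0.00004158,0.15191861
395,0.00000874,0.00008906,0.21863691
400,0.00001916,0.00018347,0.30144650
405,0.00004051,0.00036402,0.39878554
410,0.00008265,0.00069647,0.50693179
415,0.00016298,0.00128661,0.62008494
420,0.00031091,0.00229749,0.73085035
425,0.00057439,0.00397018,0.83107532
430,0.00102876,0.00664630,0.91289796
435,0.00178807,0.01078970,0.96981033
440,0.00301875,0.01700298,0.99752902
445,0.00495496,0.02603378,0.99451109
450,0.00791419,0.03876493,0.96203541
455,0.01231089,0.05618348,0.90386494
460,0.01866557,0.07932485,0.82558813
465,0.02760577,0.10919180,0.73378802
470,0.03985565,0.14665155,0.63519817
475,0.05621137,0.19231897,0.53597990
480,0.07750031,0.24643774,0.44120802
485,0.10452435,0.30877431,0.35459723
490,0.13798929,0.37854026,0.27845358
495,0.17842512,0.45435736,0.21380210
500,0.22610417,0.53427535,0.16062651
505,0.28096548,0.61584678,0.11815762
510,0.34255493,0.69625584,0.08515848
515,0.40998964,0.77249124,0.06017110
520,0.48195380,0.84154683,0.04170655
525,0.55672981,0.90063010,0.02837462
530,0.63226527,0.94735729,0.01895872
535,0.70627218,0.97991560,0.01244735
540,0.77635101,0.99717725,0.00803454
545,0.84012938,0.99875597,0.00510130
550,0.89540347,0.98500352,0.00318749
555,0.94026972,0.95695024,0.00196096
560,0.97323552,0.91619926,0.00118833
565,0.99330014,0.86478798,0.00070966
570,1.00000000,0.80503188,0.00041782
575,0.99341627,0.73936616,0.00024262
580,0.97414637,0.67019837,0.00013901
585,0.94324398,0.59978259,0.00007862
590,0.90213476,0.53012187,0.00004390
595,0.85251624,0.46290210,0.00002422
600,0.79625083,0.39945696,0.00001320
605,0.73526050,0.34076103,0.00000711
610,0.67143022,0.28744623,0.00000379
615,0.60652588,0.23983573,0.00000200
620,0.54213004,0.19798933,0.00000104
625,0.47959728,0.16175467,0.00000054
630,0.42002887,0.13081937,0.00000027
635,0.36426514,0.10476041,0.00000014
640,0.31289303,0.08308808,0.00000007
645,0.26626539,0.06528300,0.00000003
650,0.22452877,0.05082550,0.00000002
655,0.18765615,0.03921761,0.00000001
660,0.15548179,0.02999805,0.00000000
665,0.12773560,0.02275148,0.00000000
670,0.10407524,0.01711277,0.00000000
675,0.08411447,0.01276769,0.00000000
680,0.06744728,0.00945083,0.00000000
685,0.05366719,0.00694185,0.00000000
690,0.04238206,0.00506068,0.00000000
695,0.03322461,0.00366225,0.00000000
700,0.02585928,0.00263129,0.00000000
705,0.01998589,0.00187735,0.00000000
710,0.01534092,0.00133029,0.00000000
715,0.01169682,0.00093637,0.00000000
720,0.00886012,0.00065480,0.00000000
725,0.00666855,0.00045499,0.00000000
730,0.00498776,0.00031419,0.00000000
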