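wavelength_nm,relative_power
390,107.361048
395,108.262619
400,109.064635
405,109.769908
410,110.381372
415,110.902053
420,111.335051
425,111.683516
430,111.950633
435,112.139601
440,112.253623
445,112.295888
450,112.269562
455,112.177777
460,112.023622
465,111.810133
470,111.540289
475,111.217007
480,110.843132
485,110.421440
490,109.954627
495,109.445315
500,108.896042
505,108.309267
510,107.687363
515,107.032625
520,106.347260
525,105.633394
530,104.893074
535,104.128261
540,103.340839
545,102.532612
550,101.705308
555,100.860578
560,100.000000
565,99.125080
570,98.237254
575,97.337890
580,96.428288
585,95.509689
590,94.583266
595,93.650136
600,92.711358
605,91.767935
610,90.820815
615,89.870896
620,88.919026
625,87.966006
630,87.012590
635,86.059489
640,85.107372
645,84.156868
650,83.208567
655,82.263022
660,81.320751
665,80.382240
670,79.447942
675,78.518278
680,77.593641
685,76.674398
690,75.760887
695,74.853422
700,73.952294
705,73.057769
710,72.170094
715,71.289494
720,70.416175
725,69.550325
730,68.692114
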