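# synthetic extinction table (see data/README.md)
# wavelength_nm	epsilon_cm-1_uM-1
440.0	0.4
442.0	0.327206
444.0	0.264469
446.0	0.212529
448.0	0.172126
450.0	0.144
452.0	0.123699
454.0	0.106425
456.0	0.0924012
458.0	0.0818518
460.0	0.075
462.0	0.0706196
464.0	0.0671732
466.0	0.0644169
468.0	0.0621071
470.0	0.06
472.0	0.058003
474.0	0.0561934
476.0	0.0545823
478.0	0.0531808
480.0	0.052
482.0	0.0509525
484.0	0.0499776
486.0	0.0491264
488.0	0.0484501
490.0	0.048
492.0	0.0476912
494.0	0.0474176
496.0	0.0471984
498.0	0.0470528
500.0	0.047
502.0	0.0470528
504.0	0.0471984
506.0	0.0474176
508.0	0.0476912
510.0	0.048
512.0	0.0484501
514.0	0.0491264
516.0	0.0499776
518.0	0.0509525
520.0	0.052
522.0	0.053149
524.0	0.0544869
526.0	0.0560503
528.0	0.0578758
530.0	0.06
532.0	0.062756
534.0	0.0663251
536.0	0.0705162
538.0	0.0751382
540.0	0.08
542.0	0.0856915
544.0	0.0923427
546.0	0.0990726
548.0	0.105
550.0	0.110756
552.0	0.116616
554.0	0.121169
556.0	0.123
558.0	0.122271
560.0	0.120389
562.0	0.117813
564.0	0.115
566.0	0.111595
568.0	0.107141
570.0	0.101947
572.0	0.0963199
574.0	0.0905682
576.0	0.085
578.0	0.0792999
580.0	0.0732568
582.0	0.0673354
584.0	0.062
586.0	0.0572206
588.0	0.0527259
590.0	0.0486182
592.0	0.045
594.0	0.041814
596.0	0.0389267
598.0	0.0363261
600.0	0.034
602.0	0.0318663
604.0	0.0298703
606.0	0.0280412
608.0	0.026408
610.0	0.025
612.0	0.0237994
614.0	0.022741
616.0	0.0217829
618.0	0.0208832
620.0	0.02
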