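# synthetic extinction table (see data/README.md)
# wavelength_nm	epsilon_cm-1_uM-1
440.0	0.002
442.0	0.002097
444.0	0.00218933
446.0	0.002279
448.0	0.002368
450.0	0.00245833
452.0	0.002552
454.0	0.002651
456.0	0.00275733
458.0	0.002873
460.0	0.003
462.0	0.0031424
464.0	0.00330187
466.0	0.0034768
468.0	0.0036656
470.0	0.00386667
472.0	0.0040784
474.0	0.0042992
476.0	0.00452747
478.0	0.0047616
480.0	0.005
482.0	0.0052424
484.0	0.0054912
486.0	0.0057488
488.0	0.0060176
490.0	0.0063
492.0	0.0065984
494.0	0.0069152
496.0	0.0072528
498.0	0.0076136
500.0	0.008
502.0	0.00842212
504.0	0.00888753
506.0	0.00939482
508.0	0.00994259
510.0	0.0105294
512.0	0.0111539
514.0	0.0118146
516.0	0.0125101
518.0	0.0132391
520.0	0.014
522.0	0.0148092
524.0	0.0156837
526.0	0.0166232
528.0	0.0176275
530.0	0.0186964
532.0	0.0198295
534.0	0.0210267
536.0	0.0222877
538.0	0.0236122
540.0	0.025
542.0	0.0264697
544.0	0.0280434
546.0	0.0297265
548.0	0.0315239
550.0	0.0334409
552.0	0.0354826
554.0	0.0376542
556.0	0.0399609
558.0	0.0424077
560.0	0.045
562.0	0.0478104
564.0	0.0509038
566.0	0.054273
568.0	0.0579113
570.0	0.0618116
572.0	0.065967
574.0	0.0703704
576.0	0.0750151
578.0	0.0798939
580.0	0.085
582.0	0.0906268
584.0	0.0969919
586.0	0.103975
588.0	0.111454
590.0	0.11931
592.0	0.12742
594.0	0.135665
596.0	0.143924
598.0	0.152076
600.0	0.16
602.0	0.168036
604.0	0.176383
606.0	0.184712
608.0	0.192695
610.0	0.2
612.0	0.206636
614.0	0.212879
616.0	0.218804
618.0	0.224486
620.0	0.23
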