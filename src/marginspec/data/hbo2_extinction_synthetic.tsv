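# synthetic extinction table (see data/README.md)
# wavelength_nm	epsilon_cm-1_uM-1
440.0	0.25
442.0	0.220571
444.0	0.196282
446.0	0.176207
448.0	0.159422
450.0	0.145
452.0	0.132196
454.0	0.120845
456.0	0.110897
458.0	0.102299
460.0	0.095
462.0	0.0886523
464.0	0.0829568
466.0	0.0779351
468.0	0.073609
470.0	0.07
472.0	0.0669323
474.0	0.0642089
476.0	0.0618192
478.0	0.0597531
480.0	0.058
482.0	0.0565056
484.0	0.0551968
486.0	0.0540352
488.0	0.0529824
490.0	0.052
492.0	0.0510672
494.0	0.0501937
496.0	0.0493865
498.0	0.0486529
500.0	0.048
502.0	0.0473443
504.0	0.0466949
506.0	0.0461981
508.0	0.046
510.0	0.046375
512.0	0.0473333
514.0	0.048625
516.0	0.05
518.0	0.05145
520.0	0.0532
522.0	0.05535
524.0	0.058
526.0	0.0618328
528.0	0.0671208
530.0	0.0733484
532.0	0.08
534.0	0.0875842
536.0	0.0962627
538.0	0.105
540.0	0.115605
542.0	0.122
544.0	0.119672
546.0	0.115
548.0	0.108185
550.0	0.099385
552.0	0.092
554.0	0.0862251
556.0	0.0807279
558.0	0.0766167
560.0	0.075
562.0	0.0763589
564.0	0.0798737
566.0	0.0847017
568.0	0.09
570.0	0.0970751
572.0	0.105866
574.0	0.114519
576.0	0.123381
578.0	0.122536
580.0	0.108233
582.0	0.0908425
584.0	0.0690659
586.0	0.0526751
588.0	0.0398064
590.0	0.03
592.0	0.0228085
594.0	0.0172113
596.0	0.0130139
598.0	0.00953715
600.0	0.0074
602.0	0.00633062
604.0	0.00549067
606.0	0.00484542
608.0	0.00436011
610.0	0.004
612.0	0.00371952
614.0	0.00348945
616.0	0.00329964
618.0	0.00313988
620.0	0.003
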