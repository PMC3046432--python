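# synthetic extinction table (see data/README.md)
# wavelength_nm	epsilon_cm-1_uM-1
440.0	0.3
442.0	0.306034
444.0	0.311254
446.0	0.315657
448.0	0.31924
450.0	0.322
452.0	0.324334
454.0	0.326506
456.0	0.32831
458.0	0.329543
460.0	0.33
462.0	0.32688
464.0	0.31944
466.0	0.31056
468.0	0.30312
470.0	0.3
472.0	0.301563
474.0	0.305
476.0	0.308438
478.0	0.31
480.0	0.305059
482.0	0.292658
484.0	0.276427
486.0	0.26
488.0	0.242456
490.0	0.221812
492.0	0.200103
494.0	0.179367
496.0	0.1611
498.0	0.143505
500.0	0.126559
502.0	0.110715
504.0	0.0964231
506.0	0.0839154
508.0	0.0722538
510.0	0.0614744
512.0	0.0518231
514.0	0.0435462
516.0	0.0367286
518.0	0.0306
520.0	0.025119
522.0	0.0204
524.0	0.0165571
526.0	0.0136143
528.0	0.0111
530.0	0.00892857
532.0	0.0071
534.0	0.00561429
536.0	0.00443954
538.0	0.0033968
540.0	0.00248571
542.0	0.0017392
544.0	0.00119017
546.0	0.0008424
548.0	0.0005488
550.0	0.0003
552.0	0.0001152
554.0	1.36e-05
556.0	0
558.0	0
560.0	0
562.0	0
564.0	0
566.0	0
568.0	0
570.0	0
572.0	0
574.0	0
576.0	0
578.0	0
580.0	0
582.0	0
584.0	0
586.0	0
588.0	0
590.0	0
592.0	0
594.0	0
596.0	0
598.0	0
600.0	0
602.0	0
604.0	0
606.0	0
608.0	0
610.0	0
612.0	0
614.0	0
616.0	0
618.0	0
620.0	0
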