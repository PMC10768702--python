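wavelength_nm,value
380.0,0.0151500614
385.0,0.0219822323
390.0,0.0313480292
395.0,0.0439369336
400.0,0.0605243727
405.0,0.0819430077
410.0,0.109037166
415.0,0.142599585
420.0,0.183291793
425.0,0.231552155
430.0,0.287498569
435.0,0.350835554
440.0,0.42077755
445.0,0.496001025
450.0,0.57463707
455.0,0.65431331
460.0,0.732249227
465.0,0.805402809
470.0,0.870659634
475.0,0.925048984
480.0,0.965966583
485.0,0.99138085
490.0,1
495.0,0.994110042
500.0,0.976647501
505.0,0.948222261
510.0,0.909811396
515.0,0.862703419
520.0,0.808426586
525.0,0.748666805
530.0,0.68518128
535.0,0.619714021
540.0,0.553918763
545.0,0.489293845
550.0,0.427132237
555.0,0.368488441
560.0,0.314162475
565.0,0.264699836
570.0,0.22040526
575.0,0.181367372
580.0,0.147490921
585.0,0.118533289
590.0,0.0941421919
595.0,0.0738919618
600.0,0.0573164138
605.0,0.0439369336
610.0,0.0332850643
615.0,0.0249194227
620.0,0.0184372216
625.0,0.0134809934
630.0,0.00974130719
635.0,0.00695635124
640.0,0.00490924478
645.0,0.00342386627
650.0,0.0023598686
655.0,0.00160741409
660.0,0.00108202338
665.0,0.000719804298
670.0,0.000473217885
675.0,0.00030745162
680.0,0.000197406452
685.0,0.000125260696
690.0,7.85483781e-05
695.0,4.86775312e-05
700.0,2.98118404e-05
705.0,1.80433824e-05
710.0,1.07923504e-05
715.0,6.37944719e-06
720.0,3.72665317e-06
725.0,2.15141319e-06
730.0,1.22743245e-06
735.0,6.92054495e-07
740.0,3.85613216e-07
745.0,2.1234031e-07
750.0,1.15553181e-07
755.0,6.21441548e-08
760.0,3.30284039e-08
765.0,1.73477762e-08
770.0,9.00469392e-09
775.0,4.61916017e-09
780.0,2.34167171e-09
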