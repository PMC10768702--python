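wavelength_nm,value
380.0,0.000536723424
385.0,0.000845911627
390.0,0.00131445122
395.0,0.00201376591
400.0,0.00304171506
405.0,0.00452973823
410.0,0.00665078203
415.0,0.0096275849
420.0,0.0137406422
425.0,0.0193348916
430.0,0.0268238728
435.0,0.036689877
440.0,0.0494784473
445.0,0.0657856094
450.0,0.086236431
455.0,0.111454005
460.0,0.142018728
465.0,0.17841879
470.0,0.220994056
475.0,0.269876848
480.0,0.324934406
485.0,0.385718796
490.0,0.451430541
495.0,0.520902097
500.0,0.592606358
505.0,0.664693666
510.0,0.735058336
515.0,0.801432789
520.0,0.86150428
525.0,0.913046308
530.0,0.954054541
535.0,0.982875781
540.0,0.998318451
545.0,1
550.0,0.990281904
555.0,0.970074948
560.0,0.940024859
565.0,0.901075106
570.0,0.854417722
575.0,0.801432789
580.0,0.743620869
585.0,0.682532971
590.0,0.61970258
595.0,0.55658382
600.0,0.49449904
605.0,0.434598209
610.0,0.377831371
615.0,0.324934406
620.0,0.276427336
625.0,0.232623658
630.0,0.193648606
635.0,0.159463934
640.0,0.129896718
645.0,0.104669821
650.0,0.0834319493
655.0,0.0657856094
660.0,0.0513117725
665.0,0.0395904771
670.0,0.0302170496
675.0,0.0228139761
680.0,0.0170387413
685.0,0.0125881422
690.0,0.00919969388
695.0,0.00665078203
700.0,0.00475619504
705.0,0.00336460589
710.0,0.00235448728
715.0,0.00162984423
720.0,0.00111604949
725.0,0.000755976702
730.0,0.000506548428
735.0,0.000335753955
740.0,0.00022014504
745.0,0.000142785555
750.0,9.16109209e-05
755.0,5.81430522e-05
760.0,3.65036261e-05
765.0,2.26705361e-05
770.0,1.39275645e-05
775.0,8.46401001e-06
780.0,5.08820689e-06
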