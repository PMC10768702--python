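wavelength_nm,value
380.0,0.00375957728
385.0,0.00578576568
390.0,0.00875112157
395.0,0.0130091118
400.0,0.0190069583
405.0,0.0272934636
410.0,0.0385199516
415.0,0.0534310693
420.0,0.0728421991
425.0,0.0976007788
430.0,0.128530018
435.0,0.166355401
440.0,0.211616874
445.0,0.26457252
450.0,0.325102436
455.0,0.39262393
460.0,0.466030519
465.0,0.543667038
470.0,0.623351054
475.0,0.70244681
480.0,0.7779922
485.0,0.846872619
490.0,0.906028777
495.0,0.952679771
500.0,0.984539049
505.0,1
510.0,0.999258662
515.0,0.986356102
520.0,0.962184753
525.0,0.927581605
530.0,0.883720044
535.0,0.832043832
540.0,0.774188341
545.0,0.711895044
550.0,0.646925446
555.0,0.580980318
560.0,0.515629228
565.0,0.452254145
570.0,0.392009423
575.0,0.335798985
580.0,0.284270093
585.0,0.237821924
590.0,0.196626262
595.0,0.160657159
600.0,0.12972616
605.0,0.103519928
610.0,0.0816374227
615.0,0.0636243751
620.0,0.0490034544
625.0,0.0372991369
630.0,0.0280569069
635.0,0.0208568982
640.0,0.0153224627
645.0,0.0111243936
650.0,0.00798165666
655.0,0.00565950775
660.0,0.00396582181
665.0,0.00274635488
670.0,0.00187952903
675.0,0.00127118963
680.0,0.000849650982
685.0,0.00056122849
690.0,0.000366359769
695.0,0.0002363441
700.0,0.000150678287
705.0,9.49348147e-05
710.0,5.91111298e-05
715.0,3.63732356e-05
720.0,2.21189003e-05
725.0,1.32927259e-05
730.0,7.89466105e-06
735.0,4.63363531e-06
740.0,2.68768973e-06
745.0,1.54065478e-06
750.0,8.7277131e-07
755.0,4.88612427e-07
760.0,2.70332012e-07
765.0,1.47808486e-07
770.0,7.98675162e-08
775.0,4.2649104e-08
780.0,2.25070495e-08
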