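wavelength_nm,value
380.0,0.000261689082
385.0,0.000304885064
390.0,0.000345480039
395.0,0.000380755367
400.0,0.000408136441
405.0,0.000425501383
410.0,0.000431452355
415.0,0.000425501383
420.0,0.000408136441
425.0,0.000380755368
430.0,0.00034548004
435.0,0.000304885069
440.0,0.000261689098
445.0,0.000218459739
450.0,0.000177375487
455.0,0.000140072392
460.0,0.000107584423
465.0,8.03688967e-05
470.0,5.83957602e-05
475.0,4.12736343e-05
480.0,2.83862256e-05
485.0,1.90183626e-05
490.0,1.24592131e-05
495.0,8.07899316e-06
500.0,5.38306914e-06
505.0,4.05299354e-06
510.0,3.98759786e-06
515.0,5.35901265e-06
520.0,8.6986035e-06
525.0,1.50261316e-05
530.0,2.60313116e-05
535.0,4.43093103e-05
540.0,7.36395825e-05
545.0,0.00011928042
550.0,0.000188230751
555.0,0.000289389231
560.0,0.000433523874
565.0,0.000632960578
570.0,0.000900913025
575.0,0.00125041473
580.0,0.00169287645
585.0,0.00223637197
590.0,0.00288383829
595.0,0.00363144314
600.0,0.0044674034
605.0,0.00537151709
610.0,0.00631559508
615.0,0.00726485492
620.0,0.00818019032
625.0,0.00902108556
630.0,0.00974883469
635.0,0.0103296733
640.0,0.0107374458
645.0,0.0109555075
650.0,0.010977681
655.0,0.0108082241
660.0,0.0104608961
665.0,0.00995731171
670.0,0.00932483023
675.0,0.00859424805
680.0,0.00779753825
685.0,0.00696583428
690.0,0.00612779016
695.0,0.00530838381
700.0,0.00452817111
705.0,0.00380295381
710.0,0.00314379606
715.0,0.00255731168
720.0,0.0020461443
725.0,0.00160957006
730.0,0.00124416366
735.0,0.000944479877
740.0,0.000703712496
745.0,0.000514300265
750.0,0.000368456114
755.0,0.000258602479
760.0,0.000177702559
765.0,0.000119485199
770.0,7.85689727e-05
775.0,5.04981327e-05
780.0,3.17082635e-05
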