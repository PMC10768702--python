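wavelength_nm,value
380.0,0.000134549251
385.0,0.000213768419
390.0,0.000335462628
395.0,0.000519975743
400.0,0.000796086691
405.0,0.00120385999
410.0,0.00179816666
415.0,0.00265290831
420.0,0.00386592014
425.0,0.00556444503
430.0,0.00791095973
435.0,0.0111089965
440.0,0.0154084456
445.0,0.0211096565
450.0,0.0285655008
455.0,0.0381804338
460.0,0.0504055334
465.0,0.0657285286
470.0,0.0846579886
475.0,0.107701145
480.0,0.135335283
485.0,0.167973237
490.0,0.205924246
495.0,0.249352209
500.0,0.298234096
505.0,0.352321955
510.0,0.411112291
515.0,0.473826726
520.0,0.539407507
525.0,0.60653066
530.0,0.673638455
535.0,0.738991296
540.0,0.800737403
545.0,0.856996891
550.0,0.905955191
555.0,0.945959469
560.0,0.97561098
565.0,0.993846173
570.0,1
575.0,0.995012479
580.0,0.980198673
585.0,0.955997482
590.0,0.923116346
595.0,0.882496903
600.0,0.835270211
605.0,0.782704538
610.0,0.726149037
615.0,0.666976811
620.0,0.60653066
625.0,0.546074427
630.0,0.486752256
635.0,0.429557358
640.0,0.375311099
645.0,0.324652467
650.0,0.2780373
655.0,0.235746077
660.0,0.197898699
665.0,0.164474457
670.0,0.135335283
675.0,0.110250525
680.0,0.0889216175
685.0,0.0710053537
690.0,0.0561347628
695.0,0.0439369336
700.0,0.0340474547
705.0,0.0261214099
710.0,0.0198410947
715.0,0.0149207861
720.0,0.0111089965
725.0,0.00818870101
730.0,0.0059760229
735.0,0.00431784001
740.0,0.00308871541
745.0,0.00218749112
750.0,0.00153381068
755.0,0.00106476624
760.0,0.000731802419
765.0,0.000497955422
770.0,0.000335462628
775.0,0.000223745794
780.0,0.00014774836
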