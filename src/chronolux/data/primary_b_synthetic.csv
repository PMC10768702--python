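wavelength_nm,value
380.0,0.00311285384
385.0,0.00384958724
390.0,0.00466152829
395.0,0.00553007197
400.0,0.00643053255
405.0,0.00733319207
410.0,0.00820485762
415.0,0.00901079788
420.0,0.00971689609
425.0,0.0102918457
430.0,0.0107092216
435.0,0.0109492758
440.0,0.0110003294
445.0,0.0108596527
450.0,0.0105337506
455.0,0.0100380054
460.0,0.00939567111
465.0,0.00863627107
470.0,0.00779351949
475.0,0.00690294625
480.0,0.0059994543
485.0,0.00511505451
490.0,0.00427700385
495.0,0.00350651689
500.0,0.00281813892
505.0,0.00221977663
510.0,0.00171329772
515.0,0.0012955491
520.0,0.000959612841
525.0,0.000696120955
530.0,0.000494478841
535.0,0.000343891851
540.0,0.000234139448
545.0,0.000156086723
550.0,0.000101957628
555.0,6.5415441e-05
560.0,4.15044611e-05
565.0,2.6505243e-05
570.0,1.77474313e-05
575.0,1.34128e-05
580.0,1.23492369e-05
585.0,1.39060323e-05
590.0,1.77930015e-05
595.0,2.39610541e-05
600.0,3.24997035e-05
605.0,4.35471901e-05
610.0,5.72106883e-05
615.0,7.34966547e-05
620.0,9.22539133e-05
625.0,0.000113133837
630.0,0.000135572437
635.0,0.000158798119
640.0,0.000181866423
645.0,0.000203719736
650.0,0.000223266405
655.0,0.000239470618
660.0,0.000251442528
665.0,0.000258517707
670.0,0.000260316268
675.0,0.000256774659
680.0,0.000248146741
685.0,0.000234974778
690.0,0.000218034726
695.0,0.000198263185
700.0,0.000176675144
705.0,0.000154282093
710.0,0.000132019093
715.0,0.000110687441
720.0,9.09168501e-05
725.0,7.31482564e-05
730.0,5.76357289e-05
735.0,4.44640213e-05
740.0,3.35770931e-05
745.0,2.48125792e-05
750.0,1.79375341e-05
755.0,1.26816465e-05
760.0,8.76527069e-06
765.0,5.92084105e-06
770.0,3.90733375e-06
775.0,2.51830559e-06
780.0,1.58460828e-06
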