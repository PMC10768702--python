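wavelength_nm,value
380.0,1.19660947e-07
385.0,2.45125895e-07
390.0,4.89909614e-07
395.0,9.55532073e-07
400.0,1.81923962e-06
405.0,3.3819021e-06
410.0,6.13996791e-06
415.0,1.08894695e-05
420.0,1.88702026e-05
425.0,3.19565148e-05
430.0,5.28965763e-05
435.0,8.5593474e-05
440.0,0.000135408205
445.0,0.000209446679
450.0,0.000316771635
455.0,0.000468459375
460.0,0.000677406003
465.0,0.000957785853
470.0,0.00132408371
475.0,0.00178966822
480.0,0.00236494756
485.0,0.00305524387
490.0,0.00385862491
495.0,0.00476401737
500.0,0.00574997103
505.0,0.00678442298
510.0,0.00782571637
515.0,0.00882496268
520.0,0.00972962547
525.0,0.0104879849
530.0,0.0110539623
535.0,0.0113916831
540.0,0.0114791572
545.0,0.0113105671
550.0,0.0108968485
555.0,0.0102644971
560.0,0.00945278604
565.0,0.00850979563
570.0,0.00748779722
575.0,0.00643858772
580.0,0.00540932947
585.0,0.00443933166
590.0,0.0035580374
595.0,0.0027842874
600.0,0.00212675142
605.0,0.0015852788
610.0,0.00115283854
615.0,0.00081770202
620.0,0.000565560136
625.0,0.000381344654
630.0,0.000250619666
635.0,0.000160502094
640.0,0.000100145193
645.0,6.08675176e-05
650.0,3.60309577e-05
655.0,2.07699606e-05
660.0,1.16575188e-05
665.0,6.36991749e-06
670.0,3.38821293e-06
675.0,1.7541783e-06
680.0,8.83902633e-07
685.0,4.33439471e-07
690.0,2.06830842e-07
695.0,9.60368413e-08
700.0,4.33882524e-08
705.0,1.90720311e-08
710.0,8.15630548e-09
715.0,3.39347953e-09
720.0,1.37352834e-09
725.0,5.40826337e-10
730.0,2.07154595e-10
735.0,7.71858921e-11
740.0,2.7975586e-11
745.0,9.86303828e-12
750.0,3.3824065e-12
755.0,1.12828432e-12
760.0,3.66086589e-13
765.0,1.15535934e-13
770.0,3.54661769e-14
775.0,1.05894215e-14
780.0,3.07530096e-15
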