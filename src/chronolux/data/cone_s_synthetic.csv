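wavelength_nm,value
380.0,0.0463284053
385.0,0.0745712675
390.0,0.115325121
395.0,0.171358059
400.0,0.244632058
405.0,0.335544733
410.0,0.442196909
415.0,0.559898367
420.0,0.681131427
425.0,0.79612426
430.0,0.894044258
435.0,0.964640293
440.0,1
445.0,0.998806182
450.0,0.972339749
455.0,0.923744712
460.0,0.856412501
465.0,0.774838405
470.0,0.684126457
475.0,0.589465974
480.0,0.49565353
485.0,0.406719292
490.0,0.325693019
495.0,0.254518429
500.0,0.194100711
505.0,0.144454849
510.0,0.10491419
515.0,0.0743589839
520.0,0.0514315683
525.0,0.0347154818
530.0,0.0228672391
535.0,0.0146994598
540.0,0.00922117209
545.0,0.0056450525
550.0,0.00337246111
555.0,0.00196617887
560.0,0.00111865509
565.0,0.000621107097
570.0,0.000336537828
575.0,0.000177950163
580.0,9.18248018e-05
585.0,4.62400949e-05
590.0,2.27234642e-05
595.0,1.08975149e-05
600.0,5.10008616e-06
605.0,2.32929589e-06
610.0,1.03817105e-06
615.0,4.51554604e-07
620.0,1.91667617e-07
625.0,7.93933853e-08
630.0,3.20934942e-08
635.0,1.26603816e-08
640.0,4.87386722e-09
645.0,1.83103944e-09
650.0,6.71303346e-10
655.0,2.40180106e-10
660.0,8.38595177e-11
665.0,2.85735891e-11
670.0,9.50110983e-12
675.0,3.08305298e-12
680.0,9.76303274e-13
685.0,3.01707156e-13
690.0,9.09878877e-14
695.0,2.67780324e-14
700.0,7.69078816e-15
705.0,2.15556014e-15
710.0,5.89585162e-16
715.0,1.57372938e-16
720.0,4.09930914e-17
725.0,1.04204961e-17
730.0,2.58501594e-18
735.0,6.25799431e-19
740.0,1.47844172e-19
745.0,3.40855545e-20
750.0,7.66890969e-21
755.0,1.68381352e-21
760.0,3.60787487e-22
765.0,7.54407591e-23
770.0,1.53942218e-23
775.0,3.06553682e-24
780.0,5.95734076e-25
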