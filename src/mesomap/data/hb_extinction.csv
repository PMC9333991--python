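# Molar extinction coefficients of human hemoglobin, 1/(M*cm).
# Approximate compilation after the widely used OMLC tabulation
# (S. Prahl, "Optical absorption of hemoglobin"), sampled on a coarse
# wavelength grid adequate for 4-LED widefield spectroscopy. Values are
# smooth interpolants of the published curves, not bit-exact copies.
# columns: wavelength_nm, eps_hbo2, eps_hbr
wavelength_nm,eps_hbo2,eps_hbr
450,62816,68012
460,44480,60344
470,33209,53412
480,26629,45072
490,23684,37020
500,20932,26600
510,20035,22800
520,24202,21200
530,39956,24970
540,53236,27380
550,45092,43016
555,39231,52276
560,32613,53412
570,44496,45072
576,54425,38440
580,50104,37020
584,44500,40584
586,41500,41500
590,33209,43888
594,22500,42500
598,12000,40000
602,5000,33000
606,2800,20000
610,1506,9443
615,1166,7800
620,942,6509
625,740,5760
630,610,5149
640,442,4345
650,368,3750
660,320,3227
680,290,2407
700,290,1794
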