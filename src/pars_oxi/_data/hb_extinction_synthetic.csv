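# Synthetic whole-blood hemoglobin molar extinction compilation (cm^-1 M^-1).
# Reproduces the qualitative features of published HbO2/Hb spectra in the
# visible/NIR window (Soret tail below 480 nm, HbO2 double peak near 540/576 nm,
# Hb single broad peak near 555 nm, crossings near 500/545/570/584 nm, NIR
# isosbestic near 800 nm); magnitudes are approximate and intended for
# self-consistent simulation + unmixing, not for quantitative spectroscopy.
# Piecewise-linear interpolation between rows is the defined behaviour.
wavelength_nm,eps_hbo2,eps_hb
450,62816,103292
460,44000,80000
470,33000,60000
480,26600,46000
490,23000,32000
500,20900,20900
510,25000,23500
520,31500,30000
530,41500,37500
540,53236,45000
545,52000,50500
550,45000,52500
555,38000,53412
560,32620,53100
565,34500,50500
570,42000,47000
576,55540,40000
580,50000,37000
584,34000,34000
590,14000,28000
600,3200,14677
610,1800,11600
620,1200,9400
635,900,6500
650,368,3750
660,320,3227
680,276,2407
700,290,1794
720,334,1600
740,446,1400
750,518,1405
760,586,1548
780,710,1100
800,816,762
820,916,700
830,974,693
850,1058,691
880,1154,726
900,1198,761
920,1230,780
950,1150,700
980,1100,600
1000,1050,550
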