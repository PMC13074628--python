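# Liquid-water absorption coefficients at the probe's LED center wavelengths,
# derived from the Hale & Querry liquid-water optical-constants dataset via
# mu_a = 4*pi*k/lambda (lengths in cm).  Center-wavelength values only; no
# spectral integration over the finite LED bandwidth is performed.
wavelength_nm,mu_a_water_cm1
1450,28.95
1650,5.98
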