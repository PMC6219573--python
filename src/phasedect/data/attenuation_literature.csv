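# Mass attenuation coefficients mu/rho [cm^2/g], total with coherent
# scattering, transcribed from the NIST standard photon cross-section
# tabulations (XCOM standard energy grid).  Interpolated at run time by a
# log-log cubic spline for attenuation-based energy calibration.
material,energy_keV,mu_over_rho_cm2_g
water,10,5.329
water,15,1.673
water,20,0.8096
water,30,0.3756
water,40,0.2683
water,50,0.2269
pmma,10,3.357
pmma,15,1.101
pmma,20,0.5714
pmma,30,0.3032
pmma,40,0.2350
pmma,50,0.2074
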