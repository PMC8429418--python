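# Default tissue library for the metastatic-vertebra model.
#
# Optical properties (mu_a, mu_s in mm^-1; g, n dimensionless) and PDT
# threshold parameters (T in photons/cm^3; uptake_C in ug/g; eps_molar in
# M^-1 cm^-1; phi_threshold in J/mm^2) per tissue role and activation
# wavelength (nm).  Sclerotic metastasis optics are taken equal to bone.
#
# 690 nm phi_threshold values are the published ones.  No published 565 nm
# thresholds exist; the 565 nm defaults scale the 690 nm values by the
# threshold-formula ratio (eps_690*lambda_690)/(eps_565*lambda_565)
# = (33000*690)/(6724*565) = 5.99359, and may be overridden in user configs.
tissues:
  spinal_cord:
    690: {mu_s: 15.47, mu_a: 0.0216, g: 0.9, n: 1.41,
          T: 0.1e18, uptake_C: 0.13, eps_molar: 33000.0, phi_threshold: 0.02}
    565: {mu_s: 22.48, mu_a: 0.108, g: 0.9, n: 1.41,
          T: 0.1e18, uptake_C: 0.13, eps_molar: 6724.0, phi_threshold: 0.1198718}
  bone:
    690: {mu_s: 15.23, mu_a: 0.01, g: 0.9, n: 1.56,
          T: 1.0e18, uptake_C: 0.3, eps_molar: 33000.0, phi_threshold: 0.1}
    565: {mu_s: 32.09, mu_a: 0.04, g: 0.9, n: 1.56,
          T: 1.0e18, uptake_C: 0.3, eps_molar: 6724.0, phi_threshold: 0.5993588}
  metastasis_sclerotic:
    690: {mu_s: 15.23, mu_a: 0.01, g: 0.9, n: 1.56,
          T: 10.0e18, uptake_C: 0.7, eps_molar: 33000.0, phi_threshold: 0.4}
    565: {mu_s: 32.09, mu_a: 0.04, g: 0.9, n: 1.56,
          T: 10.0e18, uptake_C: 0.7, eps_molar: 6724.0, phi_threshold: 2.3974352}
  metastasis_lytic:
    690: {mu_s: 16.0, mu_a: 0.009, g: 0.9, n: 1.56,
          T: 10.0e18, uptake_C: 0.7, eps_molar: 33000.0, phi_threshold: 0.4}
    565: {mu_s: 10.22, mu_a: 0.09, g: 0.9, n: 1.56,
          T: 10.0e18, uptake_C: 0.7, eps_molar: 6724.0, phi_threshold: 2.3974352}
  muscle:
    690: {mu_s: 7.356, mu_a: 0.052, g: 0.93, n: 1.41,
          T: 1.0e18, uptake_C: 0.13, eps_molar: 33000.0, phi_threshold: 0.1}
    565: {mu_s: 11.61, mu_a: 0.36, g: 0.93, n: 1.41,
          T: 1.0e18, uptake_C: 0.13, eps_molar: 6724.0, phi_threshold: 0.5993588}
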