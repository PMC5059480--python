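# Versioned physical defaults for the command-line front end.  Every
# number that anchors the analysis to the published protocol lives here
# rather than in code.
tas:
  irf_fwhm_fs: 200.0        # Gaussian IRF, fixed during the global fit
  tau1_fs: 210.0            # fast lifetime (fit initialisation / generator)
  tau2_fs: 480.0            # slow lifetime
  mask_window_nm: [600.0, 632.0]   # pump-overtone block
  noise_sd_mOD: 0.05
  chirp_coeffs: [250.0, -0.7, 0.0005]
spectra:
  broadening_fwhm_eV: 0.7
  grid_nm: {min: 300.0, max: 750.0, step: 0.5}
dynamics:
  dt_nuclear_fs: 0.5
  dt_electronic_fs: 0.02
  t_max_fs: 1000.0
  n_traj: 137
  decoherence_C_eV: 2.7211386245988   # 0.1 hartree
  soc_cm1: {S1_T2: 160.0, S1_T1: 50.0}
populations:
  grid_dt_fs: 5.0
  n_bootstrap: 200
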