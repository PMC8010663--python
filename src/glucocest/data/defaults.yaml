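# Frozen default physical parameters for the glucoCEST forward model.
#
# Exchange rates and relaxation times of the solute pools are not measurable
# from the experiments this package emulates; they are literature-scale
# defaults (room-temperature phantom regime for the phantom water entry,
# brain tissue at 7 T for the in vivo entry).  Edit a copy of this file and
# pass it through the config loader to override; the shipped values are the
# single parameter set used for every simulation in the package.
field_T: 7.0
gamma_hz_per_uT: 42.577          # gyromagnetic ratio / 2pi, Hz per microtesla
water_proton_conc_mM: 111000.0   # 2 x 55.5 M pure water proton concentration

water:
  phantom: {T1_s: 3.0, T2_s: 1.0}    # PBS + 1% agarose
  invivo:  {T1_s: 2.0, T2_s: 0.06}   # rat brain parenchyma at 7 T

glucose:
  # Single effective hydroxyl pool; the five exchangeable OH protons of
  # D-glucose are lumped at a weighted-mean shift of +1.2 ppm.
  delta_ppm: 1.2
  protons_per_molecule: 5
  k_exch_ref_s: 2500.0    # base-catalysed exchange rate at ph_ref
  ph_ref: 7.4
  T1_s: 1.0
  T2_s: 0.01

metabolites:
  creatine:  {delta_ppm: 1.9,  protons_per_molecule: 4, k_exch_s: 810.0,  T1_s: 1.0, T2_s: 0.015}
  glutamate: {delta_ppm: 3.0,  protons_per_molecule: 3, k_exch_s: 5500.0, T1_s: 1.0, T2_s: 0.01}
  gaba:      {delta_ppm: 2.75, protons_per_molecule: 2, k_exch_s: 6000.0, T1_s: 1.0, T2_s: 0.01}
  choline:   {delta_ppm: 0.9,  protons_per_molecule: 1, k_exch_s: 2000.0, T1_s: 1.0, T2_s: 0.02}
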