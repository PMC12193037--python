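{
  "fitness": 0.6642126528151002,
  "params": {
    "C_N": 2.0842026965858436,
    "C_T": 0.2803751171779031,
    "C_m": 0.7536607389437098,
    "C_n": 0.3568725287157694,
    "I_avb": 66.42053668466866,
    "I_rib": 12.047605450856981,
    "act_Vx": -25.730414440110373,
    "act_theta": 5.615956886177395,
    "c": 0.9610965170651903,
    "g_m": 0.8438365810020273,
    "g_n": 1.2865509368924324,
    "k": 23.04788838896063,
    "nf_Vx": 4.314002769500817,
    "nf_theta": 1.964801394849867,
    "pf_Vx": 2.3652970951144066,
    "pf_theta": 1.287841311581387,
    "syn_Vx": -2.8926067920693135,
    "syn_theta": 2.3365750498198854,
    "w_avb_d": 3.68852177181281,
    "w_avb_v": 2.366756337979752,
    "w_eI_d": 2.539907119451931,
    "w_eI_v": 2.599438087523721,
    "w_eM_d": 1.7363093897300397,
    "w_eM_v": 2.3659981774838243,
    "w_gap_ee": 1.482049177935791,
    "w_gap_head": 0.6957789925803681,
    "w_gap_ii": 0.764076258275765,
    "w_gap_mm": 0.7910612940620656,
    "w_iM_d": 2.317291679215614,
    "w_iM_v": 1.6520635019323229,
    "w_ii": 2.456862349924451,
    "w_m": 50.0,
    "w_nf_d": 2.649445822807176,
    "w_nf_head": 3.165744379829813,
    "w_nf_v": 2.416371953763288,
    "w_pf": 1.0395451889734248,
    "w_pf_head": 2.572622072241685,
    "w_rib_d": 1.1384089734650156,
    "w_rib_v": 0.2910546308815445
  },
  "problem": "simplified_worm",
  "provenance": {
    "eval_seeds": 2,
    "fitness_horizon_s": 16.0,
    "generations": 40,
    "initialised_from": "rhythm-only worm fit (pop 24 x 30, seed 17), itself initialised from the functional-unit fit",
    "objective": "rhythm + muscle-count-weighted velocity deficit",
    "optimizer": "genetic algorithm",
    "population": 24,
    "seed": 29
  },
  "reference": {
    "frequency_hz": 1.006,
    "mean_adjacent_lag_s": 0.152,
    "vb_db_correlation": -0.95,
    "velocity_um_per_s": 126.1
  }
}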