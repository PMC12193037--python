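{
  "fitness": 0.0013342228152102287,
  "params": {
    "C_N": 1.3108664992735035,
    "C_T": 0.5013257451875106,
    "C_m": 0.4151297456004475,
    "C_n": 0.13689265251870109,
    "act_Vx": -9.185389203323968,
    "act_theta": 8.091387267035326,
    "c": 0.5811113717382239,
    "g_m": 1.178069110801984,
    "g_n": 0.5647094786983414,
    "input_ratio": 2.0915885337440945,
    "k": 11.432272245196952,
    "nf_Vx": 3.195701277250109,
    "nf_theta": 1.3670213329478866,
    "pf_Vx": 0.3088023002267001,
    "pf_theta": 2.5530765542410854,
    "syn_Vx": -14.042392177413397,
    "syn_theta": 6.672941343081319,
    "u1": 27.3420094567403,
    "w_eI_d": 3.234047133891524,
    "w_eI_v": 3.4477868915593612,
    "w_eM_d": 3.188452251898053,
    "w_eM_v": 0.44413979795081293,
    "w_gap_ee": 1.326071882510034,
    "w_gap_head": 0.4245671086208813,
    "w_gap_ii": 1.3577491212680604,
    "w_gap_mm": 0.6144758503315646,
    "w_iM_d": 2.4048596083206504,
    "w_iM_v": 0.2540733176713398,
    "w_ii": 3.6918099135544193,
    "w_m": 12.364868151903575,
    "w_nf_d": 3.0754597705395126,
    "w_nf_v": 1.4423086933271259,
    "w_pf": 0.9158241944381751
  },
  "problem": "coupled_body",
  "provenance": {
    "eval_seeds": 2,
    "fitness_horizon_s": 16.0,
    "generations": 25,
    "initialised_from": "functional_unit fit",
    "optimizer": "genetic algorithm",
    "population": 28,
    "seed": 13
  },
  "reference": {
    "frequency_hz": 1.0
  }
}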