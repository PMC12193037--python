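{
  "fitness": 0.009017646984051275,
  "params": {
    "C_N": 3.105581569247838,
    "C_T": 0.4864852010472804,
    "C_m": 0.24339759203309322,
    "C_n": 0.176062870033931,
    "act_Vx": -25.24493298938428,
    "act_theta": 7.514105663454259,
    "c": 0.3785151895953283,
    "g_m": 1.0249011890098356,
    "g_n": 0.9676351442990774,
    "input_ratio": 1.598554088990234,
    "k": 20.04084547968046,
    "nf_Vx": 3.624758856627691,
    "nf_theta": 1.5766122964353224,
    "pf_Vx": 2.148863426697017,
    "pf_theta": 1.7548866095378286,
    "syn_Vx": -26.2203210170418,
    "syn_theta": 6.613376582795937,
    "u1": 18.01604704270543,
    "w_eI_d": 2.0632366505091473,
    "w_eI_v": 2.1166927671308686,
    "w_eM_d": 2.6420202825581365,
    "w_eM_v": 1.0413306848124297,
    "w_gap_ee": 1.2527175491284237,
    "w_gap_head": 0.5618581844077294,
    "w_gap_ii": 1.0191154377892073,
    "w_gap_mm": 0.5721594326056341,
    "w_iM_d": 1.9357612785027705,
    "w_iM_v": 2.0613087496712836,
    "w_ii": 2.9530736368494663,
    "w_m": 20.769089908905833,
    "w_nf_d": 3.790907229090301,
    "w_nf_v": 3.014363147695436,
    "w_pf": 0.679596270011861
  },
  "problem": "coupled_head",
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
    "frequency_hz": 0.99
  }
}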