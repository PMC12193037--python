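{
  "fitness": 0.0,
  "params": {
    "C_N": 1.9100466844173571,
    "C_T": 0.737541260944371,
    "C_m": 0.15162544147344295,
    "C_n": 0.061773568744635285,
    "I_ext": 78.42679250613132,
    "act_Vx": -9.953843302913398,
    "act_theta": 6.353678555755009,
    "c": 0.31174601160411153,
    "fb_Vx": 5.854393916612262,
    "fb_theta": 0.7434567906560694,
    "g_m": 1.7107557746493587,
    "g_n": 1.1020830353517357,
    "k": 17.141897614221747,
    "nf_Vx": 5.854393916612262,
    "nf_theta": 0.7434567906560694,
    "syn_Vx": -20.81196227232855,
    "syn_theta": 5.8886347535676125,
    "w_che": 1.974106405877233,
    "w_f": 4.6039762557067245,
    "w_m": 20.092656863944633
  },
  "problem": "two_node",
  "provenance": {
    "eval_seeds": 1,
    "fitness_horizon_s": 10.0,
    "generations": 20,
    "optimizer": "genetic algorithm",
    "population": 24,
    "seed": 1
  },
  "reference": {
    "frequency_hz": 1.0
  }
}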