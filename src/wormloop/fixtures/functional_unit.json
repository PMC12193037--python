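{
  "fitness": 0.0012492192379764955,
  "params": {
    "C_N": 2.3680399779689583,
    "C_T": 0.8916599909671472,
    "C_m": 0.4281001423853339,
    "C_n": 0.07289048152704043,
    "act_Vx": -26.41561252237787,
    "act_theta": 5.9529703889923145,
    "c": 0.34404808664506864,
    "g_m": 0.9741955807155563,
    "g_n": 1.4027000220709336,
    "input_ratio": 1.6477849221022325,
    "k": 28.328049722219696,
    "nf_Vx": 3.8750506433029193,
    "nf_theta": 1.8909378811991913,
    "syn_Vx": -11.008252533870584,
    "syn_theta": 8.299379690679693,
    "u1": 54.23614139809725,
    "w_eI_d": 2.4031594112353982,
    "w_eI_v": 1.3749492858017438,
    "w_eM_d": 2.2594033525312733,
    "w_eM_v": 1.7084165093959225,
    "w_iM_d": 2.7212476528696485,
    "w_iM_v": 3.031694462603675,
    "w_ii": 0.7387487250648735,
    "w_m": 13.879650110063753,
    "w_nf_d": 2.738956332714685,
    "w_nf_v": 3.304510934183184
  },
  "problem": "functional_unit",
  "provenance": {
    "eval_seeds": 2,
    "fitness_horizon_s": 16.0,
    "generations": 30,
    "optimizer": "genetic algorithm",
    "population": 32,
    "seed": 11
  },
  "reference": {
    "amplitude_um": 14.0,
    "dorsoventral_delta_correlation": -0.98,
    "frequency_hz": 1.0,
    "vb_db_potential_correlation": -0.35
  }
}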