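{
  "params": {
    "P": 0.010000000000000002,
    "T": 1.0017740104297812,
    "U_basal": 1e-06,
    "XPbasal": 0.0,
    "Xbasal": 0.0001,
    "YT": 15.0,
    "k1": 0.085,
    "k10": 0.001,
    "k1010": 0.8,
    "k2": 0.143,
    "k3": 500.0,
    "k4": 0.0012,
    "k5": 0.0072,
    "k55": 20.0,
    "k6": 0.962,
    "k7": 0.012,
    "k8": 0.08,
    "k88": 10.0,
    "k9": 0.08,
    "lambda1": 0.0001,
    "lambda2": 0.0001
  },
  "report": {
    "achieved": {
      "unstable_xt": 9.45485704033073,
      "upper_xt": 95.00263480323022
    },
    "derived_c": 0.009540704861236012,
    "fitted": {
      "P": 0.010000000000000002,
      "c_group_T_YT": 15.026610156446718
    },
    "method": "deterministic bounded least squares on the two baseline fixed points (quartic level, condition I, lambda=1e-4/s)",
    "residuals": {
      "unstable": 0.005835855354332953,
      "upper": 2.77347708443898e-05
    },
    "seed_free": true,
    "split": {
      "T": 1.0017740104297812,
      "YT": 15.0
    },
    "stimulus_note": "No Ca4CaM pulse amplitude can switch the loop up from the resting state within 10 s: the resting kinase pool (~1e-4 uM) bounds phospho-CPEB1 production during the pulse four orders of magnitude below the separatrix level.  Up-state protocols therefore start from a supra-threshold pool of inactive kinase (up_pool_factor x the separatrix X_T) which the pulse then activates.",
    "targets": {
      "unstable_xt": 9.4,
      "upper_xt": 95.0
    }
  },
  "u_stim": 10.0,
  "up_pool_factor": 2.0
}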