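{
  "comment": "Published prediction equations for basal endogenous losses in pigs fed N-free diets. CP equations predict BEL of CP (g/kg DMI) from initial body weight (kg); AA equations predict BEL of each amino acid (g/kg DMI) from BEL of CP (g/kg DMI). ibw_range is the body-weight span of the underlying dataset.",
  "ibw_range": [9.2, 109.8],
  "cp_linear": {"C1": 20.36, "C2": -0.077, "se": [0.97, 0.020], "rmse": 4.87, "r2": 0.11, "n": 117},
  "cp_exponential": {"C1": 20.80, "C2": -0.00475, "se": [1.14, 0.00126], "rmse": 4.86, "r2": 0.12, "n": 117},
  "cp_broken_line": {"plateau": 14.78, "slope": 0.102, "breakpoint": 62.0, "rmse": 4.89, "r2": 0.12, "n": 117},
  "aa_equations": {
    "Arg": {"intercept": -0.090, "slope": 0.041, "rmse": 0.124, "r2": 0.74, "n": 117},
    "His": {"intercept": 0.060, "slope": 0.008, "rmse": 0.055, "r2": 0.35, "n": 117},
    "Ile": {"intercept": 0.140, "slope": 0.011, "rmse": 0.086, "r2": 0.31, "n": 117},
    "Leu": {"intercept": 0.231, "slope": 0.018, "rmse": 0.125, "r2": 0.35, "n": 117},
    "Lys": {"intercept": 0.148, "slope": 0.017, "rmse": 0.138, "r2": 0.28, "n": 117},
    "Met": {"intercept": 0.059, "slope": 0.002, "rmse": 0.046, "r2": 0.06, "n": 117},
    "Phe": {"intercept": 0.159, "slope": 0.011, "rmse": 0.103, "r2": 0.22, "n": 117},
    "Thr": {"intercept": 0.217, "slope": 0.020, "rmse": 0.118, "r2": 0.43, "n": 117},
    "Trp": {"intercept": 0.058, "slope": 0.004, "rmse": 0.064, "r2": 0.10, "n": 110},
    "Val": {"intercept": 0.145, "slope": 0.019, "rmse": 0.112, "r2": 0.45, "n": 117},
    "Ala": {"intercept": 0.098, "slope": 0.030, "rmse": 0.093, "r2": 0.73, "n": 116},
    "Asp": {"intercept": 0.286, "slope": 0.030, "rmse": 0.153, "r2": 0.52, "n": 114},
    "Cys": {"intercept": 0.086, "slope": 0.007, "rmse": 0.076, "r2": 0.19, "n": 113},
    "Glu": {"intercept": 0.376, "slope": 0.037, "rmse": 0.245, "r2": 0.38, "n": 113},
    "Gly": {"intercept": -0.181, "slope": 0.103, "rmse": 0.267, "r2": 0.80, "n": 113},
    "Pro": {"intercept": -3.003, "slope": 0.461, "rmse": 1.876, "r2": 0.63, "n": 98},
    "Ser": {"intercept": 0.231, "slope": 0.021, "rmse": 0.466, "r2": 0.05, "n": 114},
    "Tyr": {"intercept": 0.211, "slope": 0.021, "rmse": 0.425, "r2": 0.06, "n": 86}
  }
}
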