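{
 "blosum62": [
  0.074,
  0.025,
  0.054,
  0.054,
  0.047,
  0.074,
  0.026,
  0.068,
  0.058,
  0.099,
  0.025,
  0.045,
  0.039,
  0.034,
  0.052,
  0.057,
  0.051,
  0.073,
  0.013,
  0.032
 ],
 "swissprot": [
  0.08259085,
  0.01371509,
  0.05456002,
  0.06757433,
  0.03864251,
  0.07077786,
  0.022725,
  0.05966563,
  0.05846431,
  0.09670638,
  0.02422665,
  0.04064471,
  0.04705176,
  0.03934328,
  0.0553609,
  0.06567224,
  0.0534588,
  0.06877565,
  0.01081189,
  0.02923216
 ],
 "pf": [
  0.07879451,
  0.01516,
  0.05352221,
  0.06682981,
  0.0397062,
  0.06950711,
  0.0229198,
  0.05900921,
  0.05944221,
  0.09637281,
  0.0237718,
  0.0414386,
  0.0482904,
  0.0395639,
  0.05409781,
  0.06833641,
  0.05406871,
  0.06734171,
  0.0114135,
  0.0304133
 ],
 "alphabet": "ACDEFGHIKLMNPQRSTVWY"
}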