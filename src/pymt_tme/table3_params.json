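{
  "lambda_ThH": 1.0767e-05,
  "lambda_ThD": 2.0501e-04,
  "lambda_ThIL12": 1.0751e-05,
  "lambda_TcD": 0.0208,
  "lambda_TcIL12": 1.0123e-05,
  "lambda_TrD": 9.4550e-05,
  "lambda_DC": 0.0014,
  "lambda_DH": 1.0484e-05,
  "lambda_MIL10": 1.3208e-05,
  "lambda_MIL12": 1.3208e-05,
  "lambda_MTh": 1.0875e-05,
  "lambda_C": 0.0063,
  "lambda_CIL6": 2.1514e-04,
  "lambda_CA": 6.0466e-04,
  "lambda_A": 0.0024,
  "lambda_HD": 0.0753,
  "lambda_HN": 4.0155e-05,
  "lambda_HM": 5.5234e-04,
  "lambda_HTc": 1.8188e-04,
  "lambda_HC": 4.0155e-05,
  "lambda_IL12M": 1.0604e-05,
  "lambda_IL12D": 5.8560e-05,
  "lambda_IL12Th": 0.0084,
  "lambda_IL12Tc": 7.1527e-04,
  "lambda_IL10M": 1.2340e-05,
  "lambda_IL10D": 2.6518e-04,
  "lambda_IL10Tr": 8.4369e-04,
  "lambda_IL10Th": 0.0011,
  "lambda_IL10Tc": 1.0831e-05,
  "lambda_IL10C": 1.0842e-05,
  "lambda_IL6A": 4.1087e-04,
  "lambda_IL6M": 1.4458e-04,
  "lambda_IL6D": 0.0011,
  "delta_Th": 1.1053e-05,
  "delta_Tc": 1.0189e-05,
  "delta_Tr": 4.9935e-05,
  "delta_TN": 1.0473e-05,
  "delta_DN": 1.1051e-05,
  "delta_D": 0.3212,
  "delta_MN": 2.8489e-04,
  "delta_M": 1.0238e-05,
  "delta_C": 0.0032,
  "delta_A": 0.0024,
  "delta_N": 0.0013,
  "delta_H": 0.0012,
  "delta_IL12": 0.0107,
  "delta_IL10": 0.0012,
  "delta_IL6": 0.0013,
  "delta_ThTr": 0.0414,
  "delta_ThIL10": 1.0753e-05,
  "delta_TcTr": 0.0162,
  "delta_TcIL10": 1.0333e-05,
  "delta_DC": 1.7530e-04,
  "delta_CTc": 9.9663e-05,
  "A_TN": 1.4442e-04,
  "A_DN": 5.8773e-04,
  "A_M": 4.1504e-05
}
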