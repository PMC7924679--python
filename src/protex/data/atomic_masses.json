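{
  "H": 1.008,
  "D": 2.014,
  "HE": 4.0026,
  "LI": 6.94,
  "B": 10.81,
  "C": 12.011,
  "N": 14.007,
  "O": 15.999,
  "F": 18.998,
  "NA": 22.99,
  "MG": 24.305,
  "AL": 26.982,
  "SI": 28.085,
  "P": 30.974,
  "S": 32.06,
  "CL": 35.45,
  "K": 39.098,
  "CA": 40.078,
  "MN": 54.938,
  "FE": 55.845,
  "CO": 58.933,
  "NI": 58.693,
  "CU": 63.546,
  "ZN": 65.38,
  "SE": 78.971,
  "BR": 79.904,
  "MO": 95.95,
  "I": 126.904,
  "W": 183.84
}
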