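{
 "checksum": "50da247f0deb14fca7588e3fed80053da1415516386b482ece4e39c67f99a93a",
 "table1": {
  "putilov": {
   "A": 0.5,
   "SWA_b": 0.75,
   "SWA_d": 2.5,
   "SWA_l": 0.7,
   "SWA_u": 4.5,
   "T_b": 27.04,
   "T_d": 1.95,
   "k": 2.0,
   "phi0": 4.13,
   "t1": 7.0,
   "t2": 23.0,
   "tau": 24.0,
   "weekday_risetime": null
  },
  "wolfson": {
   "A": 0.5,
   "SWA_b": 0.75,
   "SWA_d": 2.5,
   "SWA_l": 0.7,
   "SWA_u": 4.5,
   "T_b": 25.22,
   "T_d": 2.29,
   "k": 2.0,
   "phi0": 3.66,
   "t1": 8.85,
   "t2": 24.2,
   "tau": 24.0,
   "weekday_risetime": 6.33
  }
 },
 "table2": {
  "10+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 21.67,
   "T_d": 2.41,
   "empirical": {
    "weekday_bedtime": 21.94,
    "weekday_risetime": 6.9,
    "weekend_bedtime": 22.93,
    "weekend_risetime": 8.79
   },
   "k": 2.0,
   "n": 24,
   "phi0": 3.66,
   "t1": 8.6,
   "t2": 22.85,
   "tau": 24.0,
   "weekday_risetime": 6.9
  },
  "12+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 22.86,
   "T_d": 2.56,
   "empirical": {
    "weekday_bedtime": 22.23,
    "weekday_risetime": 6.71,
    "weekend_bedtime": 23.47,
    "weekend_risetime": 9.25
   },
   "k": 2.0,
   "n": 25,
   "phi0": 3.66,
   "t1": 9.05,
   "t2": 23.45,
   "tau": 24.0,
   "weekday_risetime": 6.7
  },
  "14+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 24.8,
   "T_d": 2.61,
   "empirical": {
    "weekday_bedtime": 23.12,
    "weekday_risetime": 6.86,
    "weekend_bedtime": 24.31,
    "weekend_risetime": 9.73
   },
   "k": 2.0,
   "n": 14,
   "phi0": 3.66,
   "t1": 9.47,
   "t2": 24.28,
   "tau": 24.0,
   "weekday_risetime": 6.9
  },
  "15+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 25.12,
   "T_d": 2.47,
   "empirical": {
    "weekday_bedtime": 23.08,
    "weekday_risetime": 6.66,
    "weekend_bedtime": 24.43,
    "weekend_risetime": 9.57
   },
   "k": 2.0,
   "n": 21,
   "phi0": 3.66,
   "t1": 9.25,
   "t2": 24.37,
   "tau": 24.0,
   "weekday_risetime": 6.7
  },
  "16+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 26.14,
   "T_d": 2.55,
   "empirical": {
    "weekday_bedtime": 23.44,
    "weekday_risetime": 6.68,
    "weekend_bedtime": 24.77,
    "weekend_risetime": 9.81
   },
   "k": 2.0,
   "n": 21,
   "phi0": 3.66,
   "t1": 9.53,
   "t2": 24.78,
   "tau": 24.0,
   "weekday_risetime": 6.7
  },
  "18+": {
   "A": 0.5,
   "SWA_b": 0.755,
   "SWA_d": 2.75,
   "SWA_l": 0.7,
   "SWA_u": 5.0,
   "T_b": 27.81,
   "T_d": 2.4,
   "empirical": {
    "weekday_bedtime": 24.25,
    "weekday_risetime": 7.66,
    "weekend_bedtime": 25.42,
    "weekend_risetime": 9.8
   },
   "k": 2.0,
   "n": 18,
   "phi0": 3.66,
   "t1": 9.64,
   "t2": 25.4,
   "tau": 24.0,
   "weekday_risetime": 7.7
  },
  "6+": {
   "A": 0.5,
   "SWA_b": 0.76,
   "SWA_d": 3.0,
   "SWA_l": 0.7,
   "SWA_u": 5.5,
   "T_b": 20.4,
   "T_d": 2.42,
   "empirical": {
    "weekday_bedtime": 21.4,
    "weekday_risetime": 7.11,
    "weekend_bedtime": 22.32,
    "weekend_risetime": 8.63
   },
   "k": 2.0,
   "n": 21,
   "phi0": 3.66,
   "t1": 8.41,
   "t2": 22.23,
   "tau": 24.0,
   "weekday_risetime": 7.1
  },
  "<=6": {
   "A": 0.5,
   "SWA_b": 0.765,
   "SWA_d": 3.25,
   "SWA_l": 0.7,
   "SWA_u": 6.0,
   "T_b": 18.39,
   "T_d": 2.36,
   "empirical": {
    "weekday_bedtime": 20.42,
    "weekday_risetime": 7.26,
    "weekend_bedtime": 20.89,
    "weekend_risetime": 7.88
   },
   "k": 2.0,
   "n": 16,
   "phi0": 3.66,
   "t1": 7.79,
   "t2": 20.84,
   "tau": 24.0,
   "weekday_risetime": 7.3
  }
 },
 "version": "1.0"
}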