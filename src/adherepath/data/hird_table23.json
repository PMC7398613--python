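{
 "names": [
  "age",
  "inpatient_hospitalizations",
  "er_visits",
  "pcp_office_visits",
  "specialist_office_visits",
  "other_outpatient_services",
  "pharmacy_fills",
  "qci_score",
  "mpr",
  "pdc"
 ],
 "n": 37359,
 "means": [
  49.64,
  0.04,
  0.02,
  2.18,
  2.61,
  2.22,
  9.95,
  1.47,
  0.58,
  0.59
 ],
 "sds": [
  14.8696076949,
  0.2604726473,
  0.2014398173,
  2.4988401309,
  3.8142894489,
  4.7255745682,
  7.3720168882,
  1.1326707377,
  0.3594982615,
  0.2866007676
 ],
 "cov": [
  [
   221.105233,
   0.08965,
   -0.094017,
   2.442816,
   3.267802,
   5.864529,
   14.209445,
   4.632682,
   0.80377,
   0.761121
  ],
  [
   0.08965,
   0.067846,
   0.011868,
   0.037303,
   0.033255,
   0.113002,
   0.200045,
   0.036237,
   6.5e-05,
   -0.000166
  ],
  [
   -0.094017,
   0.011868,
   0.040578,
   0.033435,
   0.022245,
   0.075032,
   0.084031,
   0.002199,
   -0.0011,
   -0.000795
  ],
  [
   2.451662,
   0.037385,
   0.03362,
   6.244202,
   6.816085,
   7.943561,
   4.40036,
   0.10114,
   0.08775,
   0.047842
  ],
  [
   3.267802,
   0.033255,
   0.022245,
   6.805591,
   14.548804,
   15.83708,
   7.174931,
   0.076749,
   0.131478,
   0.073374
  ],
  [
   5.864529,
   0.113002,
   0.075032,
   7.918511,
   15.83708,
   22.331055,
   10.065882,
   0.274862,
   0.182628,
   0.105173
  ],
  [
   14.209445,
   0.200045,
   0.084031,
   4.385411,
   7.174931,
   10.065882,
   54.346633,
   0.771759,
   1.037027,
   0.708629
  ],
  [
   4.632682,
   0.036237,
   0.002199,
   0.101364,
   0.076749,
   0.274862,
   0.771759,
   1.282943,
   0.018688,
   0.012082
  ],
  [
   0.80377,
   6.5e-05,
   -0.0011,
   0.087459,
   0.131478,
   0.182628,
   1.037027,
   0.018688,
   0.129239,
   0.062483
  ],
  [
   0.761121,
   -0.000166,
   -0.000795,
   0.047573,
   0.073374,
   0.105173,
   0.708629,
   0.012082,
   0.062483,
   0.08214
  ]
 ],
 "medians": [
  52,
  0,
  0,
  1,
  2,
  1,
  8,
  1,
  0.66,
  0.6
 ],
 "pct_nonzero": {
  "inpatient_hospitalizations": 0.03,
  "er_visits": 0.018,
  "pcp_office_visits": 0.345,
  "specialist_office_visits": 0.508,
  "other_outpatient_services": 0.716
 },
 "length_of_stay": {
  "mean": 5.61,
  "sd": 6.8,
  "median": 4,
  "n": 1133
 }
}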