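{
 "rewards": {
  "mean": 30.0,
  "sd": 15.0,
  "units": "$/month",
  "median": 35,
  "cross_cov": {
   "age": -0.2,
   "inpatient_hospitalizations": -0.8,
   "er_visits": -0.6,
   "pcp_office_visits": 0.05,
   "specialist_office_visits": 0.1,
   "other_outpatient_services": 0.15,
   "pharmacy_fills": 0.85,
   "qci_score": 0.002,
   "mpr": 0.7,
   "pdc": 0.6
  }
 },
 "engagement_rate": {
  "mean": 234.0,
  "sd": 180.0,
  "units": "messages/month",
  "median": 265,
  "cross_cov": {
   "age": -0.1,
   "inpatient_hospitalizations": -0.6,
   "er_visits": -0.7,
   "pcp_office_visits": 0.08,
   "specialist_office_visits": 0.2,
   "other_outpatient_services": 0.26,
   "pharmacy_fills": 1.04,
   "qci_score": 0.001,
   "mpr": 0.5,
   "pdc": 0.46,
   "rewards": 0.82
  }
 }
}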