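citation_key,reference,settings,comparators,conclusion,outcome_metric,perspective,time_horizon,key_drivers
walker2013,14,Europe,stress_ecg;spect;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,prevalence
boldt2013,22,Europe,spect;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,10_30_years,prevalence
thom2014,30,Europe,stress_echo;spect;ica,unclear,cost_per_qaly_or_ly,not_stated,3_10_years,prevalence
petrov2015,25,Europe,ica,cmr_cost_effective,cost_per_qaly_or_ly,not_stated,10_30_years,
pontone2016,27,Europe,ccta,cmr_cost_effective,cost_per_qaly_or_ly,not_stated,lt_3_years,
pletscher2016,26,Europe,stress_ecg;spect;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,prevalence;test_costs
moschetti2017,24,US;Europe,ica,cmr_cost_effective,other,healthcare_system_or_payer,not_stated,prevalence;test_costs
sharples2007,28,US;Europe,stress_echo;spect;ica,unclear,cost_per_qaly_or_ly,not_stated,lt_3_years,test_costs
genders2015,20,US;Europe,no_imaging;stress_echo;spect;ccta,cmr_not_cost_effective,cost_per_qaly_or_ly,societal,lifetime,prevalence
campbell2014,23,Europe,,unclear,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,
walker2019,31,Europe,stress_ecg;spect;ccta;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lt_3_years,
bertoldi2016,21,other,stress_echo;stress_ecg;ccta,cmr_not_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,test_costs
kozor2020,32,other,spect;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,prevalence
stojanovic2014,29,US,spect,cmr_cost_effective,other,hospital,lt_3_years,prevalence
ge2020,13,US,no_imaging;spect;ccta;ica,cmr_cost_effective,cost_per_qaly_or_ly,healthcare_system_or_payer,lifetime,prevalence
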