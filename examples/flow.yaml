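# Participant flow of the five-site 2-year neurodevelopment follow-up.
# analysed is derived: assessed - excluded_medical = 1339 - 32 = 1307.
# Note: evaluated_in_window (1128 of 1307) computes to 86.3%; the study
# narrative prints 86.4% — the computed value is what flow_summary reports.
eligible: 1753
seen_at_2y: 1422
assessed: 1339
excluded_medical: 32
lost_contact: 331
evaluated_in_window: 1128
n_sites: 5
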