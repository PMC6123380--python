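# Bundled 11-patient cohort: per-patient counts of atrial regions (of 7) in
# each concordance category between simulation-predicted and clinically
# mapped driver-harboring regions, with long-term ablation outcome.
# Outcome grouping: patients are ordered by long-term outcome; success =
# patients 1-4, failure = patients 5-11 (the only grouping consistent with
# all published per-group summary statistics for this cohort).
patient,both,neither,sim_only,firm_only,outcome
1,2,3,2,0,success
2,1,6,0,0,success
3,3,4,0,0,success
4,3,2,1,1,success
5,1,4,2,0,failure
6,1,2,2,2,failure
7,1,3,2,1,failure
8,2,3,2,0,failure
9,2,3,2,0,failure
10,1,2,4,0,failure
11,3,3,1,0,failure
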