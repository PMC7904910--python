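subject_id,cohort,sitting,trial,n_correct,duration_s,event_times
P001,HV,1,1,3,90,2;4;6
P001,HV,1,2,47,90,
P002,RRMS,1,1,30,75,
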