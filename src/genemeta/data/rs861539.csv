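study_id,year,case_11,case_12,case_22,ctrl_11,ctrl_12,ctrl_22,case_source,control_source,specimen,hwe_in_controls,total_sample_size
Auranen,2005,676,762,227,1712,1946,583,mixed,population,blood,yes,5906
Beesley,2007,291,339,101,288,351,108,cancer_registry,population,blood,yes,1478
Quaye,2009,545,612,175,784,958,282,mixed,population,blood,yes,3760
Webb,2005,591,656,198,307,375,106,mixed,volunteers,mixed,yes,2233
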