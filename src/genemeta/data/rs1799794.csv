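study_id,year,case_11,case_12,case_22,ctrl_11,ctrl_12,ctrl_22,case_source,control_source,specimen,hwe_in_controls,total_sample_size
Auranen,2005,1060,550,48,2551,1188,161,mixed,population,blood,yes,5906
Quaye,2009,940,484,37,1505,713,89,mixed,population,blood,yes,3760
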