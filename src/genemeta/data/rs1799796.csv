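study_id,year,case_11,case_12,case_22,ctrl_11,ctrl_12,ctrl_22,case_source,control_source,specimen,hwe_in_controls,total_sample_size
Auranen,2005,769,692,203,1757,1776,433,mixed,population,blood,yes,5906
Quaye,2009,676,608,177,1040,1006,253,mixed,population,blood,yes,3760
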