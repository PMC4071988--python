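study_id,year,country,case_source,control_source,specimen,total_cases,total_controls,reported_quality
Auranen,2005,UK-USA,mixed,population,blood,1665,4241,14
Beesley,2007,Australia,cancer_registry,population,blood,731,747,15
Quaye,2009,DK-UK-USA,mixed,population,blood,1461,2299,14
Webb,2005,Australia,mixed,volunteers,mixed,1445,788,12
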