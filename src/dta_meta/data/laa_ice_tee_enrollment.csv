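study_id,year,design,n_ice,n_tee
Saksena,2010,prospective,95,95
Stec,2011,retrospective,12,12
Ren,2013,retrospective,56,56
Baran,2013,prospective,76,76
Anter,2014,prospective,71,69
Sriram,2015,retrospective,122,122
Baran-b,2017,prospective,21,21
Ikegami,2017,retrospective,97,107
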