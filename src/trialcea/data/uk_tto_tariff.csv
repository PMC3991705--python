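term,level,decrement
any_dysfunction,,0.081
any_level3,,0.269
mobility,2,0.069
mobility,3,0.314
self_care,2,0.104
self_care,3,0.214
usual_activities,2,0.036
usual_activities,3,0.094
pain_discomfort,2,0.123
pain_discomfort,3,0.386
anxiety_depression,2,0.071
anxiety_depression,3,0.236
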