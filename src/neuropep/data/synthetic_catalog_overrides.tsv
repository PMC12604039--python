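precursor_id	action	position	payload
PQ049300	set_role	22	bioactive_candidate
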