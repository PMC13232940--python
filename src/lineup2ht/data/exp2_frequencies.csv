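condition,lineup_type,response,count
combined_three,culprit_present,suspect,237
combined_three,culprit_present,filler,137
combined_three,culprit_present,rejection,217
combined_three,culprit_absent,suspect,23
combined_three,culprit_absent,filler,65
combined_three,culprit_absent,rejection,109
separate_three,culprit_present,suspect,229
separate_three,culprit_present,filler,147
separate_three,culprit_present,rejection,224
separate_three,culprit_absent,suspect,29
separate_three,culprit_absent,filler,54
separate_three,culprit_absent,rejection,117
combined_one,culprit_present,suspect,66
combined_one,culprit_present,filler,50
combined_one,culprit_present,rejection,76
combined_one,culprit_absent,suspect,59
combined_one,culprit_absent,filler,167
combined_one,culprit_absent,rejection,350
separate_one,culprit_present,suspect,76
separate_one,culprit_present,filler,54
separate_one,culprit_present,rejection,62
separate_one,culprit_absent,suspect,68
separate_one,culprit_absent,filler,195
separate_one,culprit_absent,rejection,313
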