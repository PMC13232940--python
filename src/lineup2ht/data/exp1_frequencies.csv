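condition,lineup_type,response,count
combined,culprit_present,suspect,284
combined,culprit_present,filler,180
combined,culprit_present,rejection,300
combined,culprit_absent,suspect,108
combined,culprit_absent,filler,257
combined,culprit_absent,rejection,399
separate,culprit_present,suspect,271
separate,culprit_present,filler,200
separate,culprit_present,rejection,297
separate,culprit_absent,suspect,86
separate,culprit_absent,filler,242
separate,culprit_absent,rejection,440
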