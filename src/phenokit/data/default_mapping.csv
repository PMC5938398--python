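source_dialect,source_code,trait_id,value_rule,value_kind
status,true_leaves,true_leaf_presence,status_to_range,count
status,unfolded_leaves,unfolded_true_leaf_presence,status_to_range,count
status,senescing_leaves,senescing_true_leaf_presence,status_to_range,count
status,flowers,flower_presence,status_to_range,count
status,open_flowers,open_flower_presence,status_to_range,count
status,fruits,fruit_presence,status_to_range,count
event,BBCH11,true_leaf_presence,event_onset,
event,BBCH60,flower_presence,event_onset,
event,BBCH87,ripe_fruit_presence,event_onset,
event,BBCH99,,excluded_agricultural,
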