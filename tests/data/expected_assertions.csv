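observation_id,class_id
obs01,true_leaf_presence:present
obs01,unfolded_true_leaf_presence:present
obs02,unfolded_true_leaf_presence:absent
obs03,breaking_leaf_bud_presence:absent
obs03,expanding_true_leaf_presence:absent
obs03,senescing_true_leaf_presence:absent
obs03,true_leaf_presence:absent
obs03,unfolded_true_leaf_presence:absent
obs03,unfolding_true_leaf_presence:absent
obs04,breaking_leaf_bud_presence:present
obs04,leaf_bud_presence:present
obs04,true_leaf_presence:present
obs04,unfolding_true_leaf_presence:present
obs05,breaking_leaf_bud_presence:absent
obs05,dormant_leaf_bud_presence:absent
obs05,leaf_bud_presence:absent
obs05,swelling_leaf_bud_presence:absent
obs06,dormant_leaf_bud_presence:present
obs06,leaf_bud_presence:present
obs07,flower_presence:present
obs08,flower_presence:absent
obs08,open_flower_presence:absent
obs08,senesced_flower_presence:absent
obs09,flower_presence:present
obs09,open_flower_presence:present
obs11,fruit_presence:present
obs11,ripe_fruit_presence:present
obs12,fruit_presence:absent
obs12,ripe_fruit_presence:absent
obs13,cone_presence:present
obs13,pollen_cone_presence:present
obs14,cone_presence:absent
obs14,pollen_cone_presence:absent
obs14,ripe_seed_cone_presence:absent
obs14,seed_cone_presence:absent
obs15,cone_presence:present
obs15,ripe_seed_cone_presence:present
obs15,seed_cone_presence:present
obs16,ripe_seed_cone_presence:absent
obs16,seed_cone_presence:absent
obs17,abscised_leaf_presence:present
obs18,abscised_leaf_presence:absent
obs19,senescing_true_leaf_presence:present
obs19,true_leaf_presence:present
obs21,senescing_true_leaf_presence:absent
obs21,true_leaf_presence:present
obs22,open_flower_presence:absent
obs22,true_leaf_presence:present
obs22,unfolding_true_leaf_presence:present
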