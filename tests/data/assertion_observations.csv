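observation_id,subject_id,genus,species,latitude,longitude,date,trait_id,value_kind,lower,upper,source,source_record_id
obs01,plant_fx01,Helianthus,annuus,29.6,-82.3,2017-06-15,unfolded_true_leaf_presence,count,10,20,other,fx01
obs02,plant_fx02,Helianthus,annuus,29.6,-82.3,2017-06-15,unfolded_true_leaf_presence,count,0,0,other,fx02
obs03,plant_fx03,Acer,rubrum,45.1,-93.2,2017-02-01,true_leaf_presence,count,0,0,other,fx03
obs04,plant_fx04,Acer,rubrum,45.1,-93.2,2017-04-20,breaking_leaf_bud_presence,count,1,5,other,fx04
obs05,plant_fx05,Acer,rubrum,45.1,-93.2,2017-07-01,leaf_bud_presence,count,0,0,other,fx05
obs06,plant_fx06,Quercus,alba,38.9,-77.0,2017-01-10,dormant_leaf_bud_presence,count,2,2,other,fx06
obs07,station:pop_fx07,Syringa,vulgaris,48.2,16.4,2017-05-12,flower_presence,percent,80,80,other,fx07
obs08,station:pop_fx08,Syringa,vulgaris,48.2,16.4,2017-01-12,flower_presence,percent,0,0,other,fx08
obs09,plant_fx09,Syringa,vulgaris,48.2,16.4,2017-05-01,open_flower_presence,percent,0.5,10,other,fx09
obs10,plant_fx10,Syringa,vulgaris,48.2,16.4,2017-06-20,senesced_flower_presence,count,0,3,other,fx10
obs11,plant_fx11,Malus,domestica,52.5,13.4,2017-09-10,ripe_fruit_presence,count,7,,other,fx11
obs12,plant_fx12,Malus,domestica,52.5,13.4,2017-03-10,fruit_presence,count,0,0,other,fx12
obs13,plant_fx13,Pinus,strobus,44.3,-71.3,2017-06-01,pollen_cone_presence,count,12,30,other,fx13
obs14,plant_fx14,Pinus,strobus,44.3,-71.3,2017-01-05,cone_presence,count,0,0,other,fx14
obs15,plant_fx15,Pinus,strobus,44.3,-71.3,2017-10-01,ripe_seed_cone_presence,count,1,1,other,fx15
obs16,plant_fx16,Picea,abies,60.2,24.9,2017-02-14,seed_cone_presence,count,0,0,other,fx16
obs17,plant_fx17,Quercus,alba,38.9,-77.0,2017-11-15,abscised_leaf_presence,count,100,200,other,fx17
obs18,plant_fx18,Quercus,alba,38.9,-77.0,2017-06-15,abscised_leaf_presence,count,0,0,other,fx18
obs19,plant_fx19,Acer,saccharum,44.0,-72.7,2017-09-25,senescing_true_leaf_presence,percent,25,75,other,fx19
obs20,plant_fx20,Acer,saccharum,44.0,-72.7,2017-03-30,swelling_leaf_bud_presence,count,0,4,other,fx20
obs21,plant_fx21,Quercus,robur,51.5,-0.1,2017-07-04,true_leaf_presence,count,15,,other,fx21
obs21,plant_fx21,Quercus,robur,51.5,-0.1,2017-07-04,senescing_true_leaf_presence,count,0,0,other,fx21
obs22,plant_fx22,Acer,platanoides,59.3,18.1,2017-05-05,unfolding_true_leaf_presence,count,3,8,other,fx22
obs22,plant_fx22,Acer,platanoides,59.3,18.1,2017-05-05,open_flower_presence,percent,0,0,other,fx22
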