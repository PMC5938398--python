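record_kind	subject_id	object_id	label	modality
structure	shoot_system		shoot system
structure	leaf_bud		leaf bud
structure	dormant_leaf_bud		dormant leaf bud
structure	swelling_leaf_bud		swelling leaf bud
structure	breaking_leaf_bud		breaking leaf bud
structure	true_leaf		true leaf
structure	unfolding_true_leaf		unfolding true leaf
structure	unfolded_true_leaf		unfolded true leaf
structure	expanding_true_leaf		expanding true leaf
structure	senescing_true_leaf		senescing true leaf
structure	flower		flower
structure	open_flower		open flower
structure	senesced_flower		senesced flower
structure	fruit		fruit
structure	ripe_fruit		ripe fruit
structure	cone		cone
structure	pollen_cone		pollen cone
structure	seed_cone		seed cone
structure	ripe_seed_cone		ripe seed cone
subclass	dormant_leaf_bud	leaf_bud
subclass	swelling_leaf_bud	leaf_bud
subclass	breaking_leaf_bud	leaf_bud
subclass	unfolding_true_leaf	true_leaf
subclass	unfolded_true_leaf	true_leaf
subclass	expanding_true_leaf	true_leaf
subclass	senescing_true_leaf	true_leaf
subclass	open_flower	flower
subclass	senesced_flower	flower
subclass	ripe_fruit	fruit
subclass	pollen_cone	cone
subclass	seed_cone	cone
subclass	ripe_seed_cone	seed_cone
part	breaking_leaf_bud	unfolding_true_leaf
trait	shoot_system_presence	shoot_system	shoot system presence	attached
trait	leaf_bud_presence	leaf_bud	leaf bud presence	attached
trait	dormant_leaf_bud_presence	dormant_leaf_bud	dormant leaf bud presence	attached
trait	swelling_leaf_bud_presence	swelling_leaf_bud	swelling leaf bud presence	attached
trait	breaking_leaf_bud_presence	breaking_leaf_bud	breaking leaf bud presence	attached
trait	true_leaf_presence	true_leaf	true leaf presence	attached
trait	unfolding_true_leaf_presence	unfolding_true_leaf	unfolding true leaf presence	attached
trait	unfolded_true_leaf_presence	unfolded_true_leaf	unfolded true leaf presence	attached
trait	expanding_true_leaf_presence	expanding_true_leaf	expanding true leaf presence	attached
trait	senescing_true_leaf_presence	senescing_true_leaf	senescing true leaf presence	attached
trait	flower_presence	flower	flower presence	attached
trait	open_flower_presence	open_flower	open flower presence	attached
trait	senesced_flower_presence	senesced_flower	senesced flower presence	attached
trait	fruit_presence	fruit	fruit presence	attached
trait	ripe_fruit_presence	ripe_fruit	ripe fruit presence	attached
trait	cone_presence	cone	cone presence	attached
trait	pollen_cone_presence	pollen_cone	pollen cone presence	attached
trait	seed_cone_presence	seed_cone	seed cone presence	attached
trait	ripe_seed_cone_presence	ripe_seed_cone	ripe seed cone presence	attached
trait	abscised_leaf_presence	true_leaf	abscised leaf presence	abscised
trait	abscised_fruit_presence	fruit	abscised fruit presence	abscised
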