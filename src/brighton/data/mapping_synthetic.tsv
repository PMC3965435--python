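code	atom	asserted_status	is_anaphylaxis_diagnosis_term
sudden_onset	sudden_onset	present	false
rapid_progression	rapid_progression	present	false
generalized_urticaria	generalized_urticaria	present	false
generalized_erythema	generalized_erythema	present	false
angioedema	angioedema	present	false
generalized_pruritus	generalized_pruritus	present	false
skin_rash	skin_rash	present	false
generalized_prickle_sensation	generalized_prickle_sensation	present	false
localized_injection_site_urticaria	localized_injection_site_urticaria	present	false
red_itchy_eyes	red_itchy_eyes	present	false
measured_hypotension	measured_hypotension	present	false
tachycardia	tachycardia	present	false
capillary_refill_gt3s	capillary_refill_gt3s	present	false
reduced_central_pulse_volume	reduced_central_pulse_volume	present	false
decreased_consciousness	decreased_consciousness	present	false
bilateral_wheeze	bilateral_wheeze	present	false
stridor	stridor	present	false
upper_airway_swelling	upper_airway_swelling	present	false
tachypnoea	tachypnoea	present	false
accessory_muscle_use	accessory_muscle_use	present	false
chest_wall_recession	chest_wall_recession	present	false
cyanosis	cyanosis	present	false
grunting	grunting	present	false
persistent_dry_cough	persistent_dry_cough	present	false
hoarse_voice	hoarse_voice	present	false
difficulty_breathing	difficulty_breathing	present	false
sensation_of_throat_closure	sensation_of_throat_closure	present	false
sneezing_rhinorrhea	sneezing_rhinorrhea	present	false
diarrhea	diarrhea	present	false
abdominal_pain	abdominal_pain	present	false
nausea	nausea	present	false
vomiting	vomiting	present	false
elevated_mast_cell_tryptase	elevated_mast_cell_tryptase	present	false
generalized_pruritus_with_skin_rash	generalized_pruritus	present	false
generalized_pruritus_with_skin_rash	skin_rash	present	false
generalized_pruritus_without_skin_rash	generalized_pruritus	present	false
generalized_pruritus_without_skin_rash	skin_rash	absent	false
capillary_refill_gt3s_without_hypotension	capillary_refill_gt3s	present	false
capillary_refill_gt3s_without_hypotension	measured_hypotension	absent	false
difficulty_breathing_without_wheeze_or_stridor	difficulty_breathing	present	false
difficulty_breathing_without_wheeze_or_stridor	bilateral_wheeze	absent	false
difficulty_breathing_without_wheeze_or_stridor	stridor	absent	false
anaphylaxis			true
anaphylactic_reaction			true
anaphylactic_shock			true
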